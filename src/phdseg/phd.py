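"""The Perceptual Hausdorff Distance (PHD).

PHD compares two skeleton point-sets the way a human observer compares two
membrane drawings: it is a modified (directed-mean) Hausdorff distance whose
per-pair distances pass through a *tolerance distance* Psi that forgives
misalignments up to a threshold ``tau``:

    Psi(x, y) = f_plus(d(x, y))   if d(x, y) >  tau
              = f_minus(d(x, y))  if d(x, y) <= tau

with Euclidean pixel distance d.  The defaults f_plus(d) = d and
f_minus(d) = 0 act like a ReLU gate on distance.  The symmetric metric sums
the two directed mean nearest-neighbour terms:

    PHD(X, Y) = (1/|X|) sum_x min_y Psi(x, y) + (1/|Y|) sum_y min_x Psi(x, y)

Averaging (rather than taking the max) makes the metric robust to outliers
and sensitive to global structure; ``tau`` encodes human tolerance for small
offsets.  A tolerance of 3 px gives the best agreement with human preference
judgements and is the evaluation default; the training losses default to
``tau = 2`` (see :mod:`phdseg.losses`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .skeleton import PointSet

__all__ = [
    "ToleranceSpec",
    "tolerance_distance",
    "phd_distance",
    "phd_bruteforce_oracle",
    "phd_curve",
    "EmptyPointSetError",
    "EVAL_TAU_DEFAULT",
    "LOSS_TAU_DEFAULT",
]

#: Tolerance used when *evaluating* segmentations (best human consistency).
EVAL_TAU_DEFAULT = 3.0
#: Tolerance used inside the training losses (best segmentation quality).
LOSS_TAU_DEFAULT = 2.0


class EmptyPointSetError(ValueError):
    """PHD is undefined on empty point-sets; names the offending side."""


def _identity(d: np.ndarray) -> np.ndarray:
    return d


def _zero(d: np.ndarray) -> np.ndarray:
    return np.zeros_like(d)


@dataclass(frozen=True)
class ToleranceSpec:
    """Tolerance threshold ``tau`` plus the f+/f- pair defining Psi.

    ``f_plus`` (applied above tau) must be non-negative and monotone;
    ``f_minus`` (applied at or below tau) must be non-negative.  Both are
    vectorized maps on arrays of distances.  Defaults are the ReLU-like pair
    f+(d) = d, f-(d) = 0.
    """

    tau: float = EVAL_TAU_DEFAULT
    f_plus: Callable[[np.ndarray], np.ndarray] = field(default=_identity)
    f_minus: Callable[[np.ndarray], np.ndarray] = field(default=_zero)

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")

    def psi(self, d: np.ndarray) -> np.ndarray:
        """Apply the tolerance distance to an array of Euclidean distances."""
        d = np.asarray(d, dtype=np.float64)
        above = d > self.tau
        out = np.where(above, self.f_plus(d), self.f_minus(d))
        if (out < 0).any():
            raise ValueError("f_plus/f_minus must be non-negative")
        return out


def tolerance_distance(x: Sequence[float], y: Sequence[float], spec: ToleranceSpec) -> float:
    """Psi between two points: f+(d) strictly above tau, f-(d) at or below."""
    d = float(np.hypot(x[0] - y[0], x[1] - y[1]))
    return float(spec.psi(np.array(d)))


def _check_nonempty(X: PointSet, Y: PointSet) -> None:
    if len(X) == 0 and len(Y) == 0:
        raise EmptyPointSetError("both point-sets are empty")
    if len(X) == 0:
        raise EmptyPointSetError("first point-set (X) is empty")
    if len(Y) == 0:
        raise EmptyPointSetError("second point-set (Y) is empty")


def nearest_neighbour_distances(X: PointSet, Y: PointSet) -> np.ndarray:
    """Euclidean distance from each point of X to its nearest point of Y."""
    _check_nonempty(X, Y)
    tree = cKDTree(Y.coords.astype(np.float64))
    d, _ = tree.query(X.coords.astype(np.float64), k=1)
    return np.atleast_1d(d)


def phd_distance(X: PointSet, Y: PointSet, spec: ToleranceSpec | None = None) -> float:
    """Perceptual Hausdorff distance between two non-empty point-sets.

    Sum of the two directed mean tolerance-gated nearest-neighbour distances.
    Symmetric, zero iff every nearest-neighbour distance in both directions
    is forgiven (<= tau under the default f-pair), and non-increasing in tau.

    Raises :class:`EmptyPointSetError` if either side is empty — callers own
    the empty-set policy (the training losses substitute a finite penalty).
    """
    spec = spec if spec is not None else ToleranceSpec()
    _check_nonempty(X, Y)
    d_xy = nearest_neighbour_distances(X, Y)
    d_yx = nearest_neighbour_distances(Y, X)
    return float(spec.psi(d_xy).mean() + spec.psi(d_yx).mean())


def phd_bruteforce_oracle(X: PointSet, Y: PointSet, spec: ToleranceSpec | None = None) -> float:
    """Reference PHD via the literal all-pairs double loop (tests only).

    Same contract as :func:`phd_distance`; quadratic cost, guarded to
    |X|*|Y| <= 1e6.
    """
    spec = spec if spec is not None else ToleranceSpec()
    _check_nonempty(X, Y)
    if len(X) * len(Y) > 10**6:
        raise ValueError("brute-force oracle limited to |X|*|Y| <= 1e6")
    xs = X.coords.astype(np.float64)
    ys = Y.coords.astype(np.float64)
    pair_d = np.sqrt(((xs[:, None, :] - ys[None, :, :]) ** 2).sum(axis=2))
    psi = spec.psi(pair_d)
    return float(psi.min(axis=1).mean() + psi.min(axis=0).mean())


def phd_curve(
    X: PointSet,
    Y: PointSet,
    taus: Sequence[float],
    f_plus: Callable[[np.ndarray], np.ndarray] = _identity,
    f_minus: Callable[[np.ndarray], np.ndarray] = _zero,
) -> list[tuple[float, float]]:
    """PHD evaluated at a sorted ascending sequence of tolerance thresholds.

    With the default f-pair the curve is non-increasing in tau and reaches 0
    exactly once tau is at least the maximum nearest-neighbour separation in
    either direction.  Nearest-neighbour distances are computed once and
    re-gated per tau.
    """
    taus = [float(t) for t in taus]
    if any(b < a for a, b in zip(taus, taus[1:])):
        raise ValueError("taus must be sorted ascending")
    d_xy = nearest_neighbour_distances(X, Y)
    d_yx = nearest_neighbour_distances(Y, X)
    out = []
    for tau in taus:
        spec = ToleranceSpec(tau=tau, f_plus=f_plus, f_minus=f_minus)
        out.append((tau, float(spec.psi(d_xy).mean() + spec.psi(d_yx).mean())))
    return out
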