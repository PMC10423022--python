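"""Training losses: pixel-wise (Dice + weighted cross-entropy), structural
PHD loss, global-local similarity loss, and the coarse-to-fine schedule.

The total training objective is

    L = L_pixel + lambda1 * L_phd + lambda2 * L_sim

where L_pixel measures per-pixel accuracy (soft Dice plus class-weighted
cross-entropy over the two classes membrane/background), L_phd the PHD
between predicted and ground-truth skeletons in both the global and local
branches, and L_sim the PHD between the global skeleton and the stitched
local skeletons.  Training is coarse-to-fine: lambda1 and lambda2 are zero
for the first ``k`` warm-up epochs (default 5) and then ramp up linearly.

The structural losses are not differentiable through binarization and
thinning; gradients use a straight-through scheme (see
:func:`phd_pointset_grad`): the skeleton pipeline acts as a selection mask
and each selected pixel receives the gradient of its own contribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import BinaryMask, ProbMap
from .phd import LOSS_TAU_DEFAULT, ToleranceSpec, nearest_neighbour_distances, phd_distance
from .skeleton import PointSet, mask_to_pointset, soft_skeleton

__all__ = [
    "ClassWeighting",
    "LossSchedule",
    "pixel_loss",
    "pixel_loss_grad",
    "phd_loss",
    "similarity_loss",
    "schedule_weights",
    "total_loss",
    "phd_with_fallback",
    "phd_pointset_grad",
]

_EPS = np.finfo(np.float64).eps


@dataclass(frozen=True)
class ClassWeighting:
    """Per-class weights for the cross-entropy term (C = 2: background, membrane).

    The convention is w_c = 1 / (class frequency in the training set), so the
    rarer membrane class is up-weighted.  ``uniform()`` gives w = (1, 1).
    """

    weights: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.weights) != 2 or any(w <= 0 for w in self.weights):
            raise ValueError("need exactly 2 strictly positive class weights")

    @staticmethod
    def uniform() -> "ClassWeighting":
        return ClassWeighting((1.0, 1.0))

    @staticmethod
    def from_masks(masks: Sequence[BinaryMask]) -> "ClassWeighting":
        """Reciprocal class frequencies pooled over a training set."""
        fg = sum(int(m.grid.sum()) for m in masks)
        total = sum(m.grid.size for m in masks)
        bg = total - fg
        if fg == 0 or bg == 0:
            raise ValueError("training set must contain both classes")
        return ClassWeighting((total / bg, total / fg))


@dataclass(frozen=True)
class LossSchedule:
    """Coarse-to-fine weight schedule for (lambda1, lambda2).

    ``warmup_epochs`` (k) epochs of pixel-only training, then each weight
    ramps linearly: lambda(e) = min(cap, rate * (e - k + 1)).  Defaults:
    k = 5, rate 0.1 per epoch, cap 1.0 for both structural losses.
    """

    warmup_epochs: int = 5
    ramp: tuple[float, float] = (0.1, 0.1)
    caps: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.warmup_epochs < 0:
            raise ValueError("warmup_epochs must be >= 0")
        if any(r < 0 for r in self.ramp) or any(c < 0 for c in self.caps):
            raise ValueError("ramp rates and caps must be >= 0")


def schedule_weights(epoch: int, sched: LossSchedule | None = None) -> tuple[float, float]:
    """(lambda1, lambda2) at a given epoch: (0, 0) during warm-up, then linear ramp."""
    sched = sched if sched is not None else LossSchedule()
    if epoch < sched.warmup_epochs:
        return (0.0, 0.0)
    step = epoch - sched.warmup_epochs + 1
    return (
        min(sched.caps[0], sched.ramp[0] * step),
        min(sched.caps[1], sched.ramp[1] * step),
    )


def total_loss(components: tuple[float, float, float], weights: tuple[float, float]) -> float:
    """L = L_pixel + lambda1 * L_phd + lambda2 * L_sim."""
    l_pixel, l_phd, l_sim = components
    lam1, lam2 = weights
    return l_pixel + lam1 * l_phd + lam2 * l_sim


def _stack_probs(s: np.ndarray | Sequence[ProbMap]) -> np.ndarray:
    if isinstance(s, np.ndarray):
        arr = s.astype(np.float64, copy=False)
    else:
        arr = np.stack([m.grid for m in s])
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ValueError(f"expected per-class probabilities of shape (2, H, W), got {arr.shape}")
    return arr


def _one_hot(g: BinaryMask) -> np.ndarray:
    fg = g.grid.astype(np.float64)
    return np.stack([1.0 - fg, fg])


def pixel_loss(s: np.ndarray | Sequence[ProbMap], g: BinaryMask,
               w: ClassWeighting | None = None) -> float:
    """Soft Dice plus class-weighted cross-entropy.

    ``s`` holds the two per-pixel class probabilities (background, membrane),
    summing to 1 per pixel; ``g`` the binary ground truth.  The Dice term is
    1 - 2*sum(g*s) / (sum(g) + sum(s)) with the sums pooled over both classes
    and all pixels; the WCE term is -(1/M) sum_i sum_c w_c g_ic log s_ic with
    the log clamped at machine epsilon.  Zero for a perfect one-hot prediction.
    """
    w = w if w is not None else ClassWeighting.uniform()
    arr = _stack_probs(s)
    gh = _one_hot(g)
    if arr.shape != gh.shape:
        raise ValueError(f"shape mismatch: probs {arr.shape} vs labels {gh.shape}")
    m = float(g.grid.size)
    dice = 1.0 - 2.0 * float((gh * arr).sum()) / (float(gh.sum()) + float(arr.sum()))
    logs = np.log(np.maximum(arr, _EPS))
    wc = np.array(w.weights, dtype=np.float64)[:, None, None]
    wce = -float((wc * gh * logs).sum()) / m
    return dice + wce


def pixel_loss_grad(s: np.ndarray, g: BinaryMask,
                    w: ClassWeighting | None = None) -> tuple[float, np.ndarray]:
    """Pixel loss and its analytic gradient w.r.t. the class probabilities."""
    w = w if w is not None else ClassWeighting.uniform()
    arr = _stack_probs(s)
    gh = _one_hot(g)
    m = float(g.grid.size)
    p_sum = float((gh * arr).sum())
    q_sum = float(gh.sum()) + float(arr.sum())
    dice = 1.0 - 2.0 * p_sum / q_sum
    clamped = np.maximum(arr, _EPS)
    wc = np.array(w.weights, dtype=np.float64)[:, None, None]
    wce = -float((wc * gh * np.log(clamped)).sum()) / m
    grad = (-2.0 * gh / q_sum + 2.0 * p_sum / q_sum**2) - (wc * gh) / (m * clamped)
    return dice + wce, grad


def _diagonal(shape: tuple[int, int]) -> float:
    return float(np.hypot(shape[0], shape[1]))


def phd_with_fallback(X: PointSet, Y: PointSet, spec: ToleranceSpec,
                      frame: tuple[int, int]) -> float:
    """PHD that never raises: an empty side costs the frame diagonal.

    The metric itself is undefined on empty point-sets; during training an
    all-background prediction must yield a large finite penalty instead of a
    crash, so one empty side is charged the image diagonal length and two
    empty sides cost 0 (nothing to match).
    """
    if len(X) == 0 and len(Y) == 0:
        return 0.0
    if len(X) == 0 or len(Y) == 0:
        return _diagonal(frame)
    return phd_distance(X, Y, spec)


def phd_loss(pred_global: ProbMap, pred_locals: Sequence[ProbMap],
             gt_global: BinaryMask, gt_locals: Sequence[BinaryMask],
             spec: ToleranceSpec | None = None, threshold: float = 0.5) -> float:
    """Structural loss: PHD(pred, gt) in the global branch plus the local branch.

    The global term compares the soft-skeleton of the global prediction with
    the ground-truth skeleton.  The local term averages the per-patch PHD
    over patches where both skeletons are non-empty, so its scale does not
    depend on the patch count; an empty prediction skeleton against non-empty
    ground truth falls back to the frame-diagonal penalty.
    """
    spec = spec if spec is not None else ToleranceSpec(tau=LOSS_TAU_DEFAULT)
    if len(pred_locals) != len(gt_locals):
        raise ValueError("pred_locals and gt_locals must align")
    Xg = soft_skeleton(pred_global, threshold)
    Yg = mask_to_pointset(gt_global, skeletonize=True)
    loss = phd_with_fallback(Xg, Yg, spec, gt_global.shape)

    per_patch = []
    for p, g in zip(pred_locals, gt_locals):
        Xl = soft_skeleton(p, threshold)
        Yl = mask_to_pointset(g, skeletonize=True)
        if len(Xl) and len(Yl):
            per_patch.append(phd_distance(Xl, Yl, spec))
        elif len(Yl):  # prediction vanished where structure exists
            per_patch.append(_diagonal(g.shape))
    if per_patch:
        loss += float(np.mean(per_patch))
    return loss


def similarity_loss(pred_global: ProbMap, pred_locals: Sequence[ProbMap],
                    grid: "PatchGrid", spec: ToleranceSpec | None = None,
                    threshold: float = 0.5) -> float:
    """Cross-scale consistency: PHD between global and stitched local skeletons.

    Local skeleton point-sets are translated by their patch anchors into the
    global frame and unioned; the loss is PHD(X_global, X_hat_local) with the
    empty-side fallback of :func:`phd_with_fallback`.
    """
    from .psnet import PatchGrid  # local import to avoid a module cycle

    assert isinstance(grid, PatchGrid)
    spec = spec if spec is not None else ToleranceSpec(tau=LOSS_TAU_DEFAULT)
    Xg = soft_skeleton(pred_global, threshold)
    Xhat = stitch_pointsets([soft_skeleton(p, threshold) for p in pred_locals], grid)
    return phd_with_fallback(Xg, Xhat, spec, grid.frame)


def stitch_pointsets(local_sets: Sequence[PointSet], grid: "PatchGrid") -> PointSet:
    """Translate per-patch point-sets by their anchors and union them."""
    if len(local_sets) != len(grid.offsets):
        raise ValueError(f"expected {len(grid.offsets)} point-sets, got {len(local_sets)}")
    shifted = [ps.translated(dr, dc, grid.frame) for ps, (dr, dc) in zip(local_sets, grid.offsets)]
    return PointSet.union(shifted, grid.frame)


def phd_pointset_grad(X: PointSet, Y: PointSet, spec: ToleranceSpec,
                      frame: tuple[int, int]) -> tuple[float, np.ndarray]:
    """PHD with a straight-through gradient on the membrane-probability plane.

    Returns ``(value, grad)`` where grad is an HxW array to be added to
    dL/d(membrane probability).  Each surviving predicted-skeleton pixel x
    carries the gradient of its own contribution Psi(x, Y)/|X| (positive:
    lowering its probability removes a badly placed pixel); each ground-truth
    skeleton pixel y carries -Psi(y, X)/|Y| (negative: raising probability
    near missing structure reduces the loss).  Empty sides use the diagonal
    fallback with the analogous sign convention.
    """
    grad = np.zeros(frame, dtype=np.float64)
    if len(X) == 0 and len(Y) == 0:
        return 0.0, grad
    diag = _diagonal(frame)
    if len(X) == 0:
        grad[Y.coords[:, 0], Y.coords[:, 1]] -= diag / len(Y)
        return diag, grad
    if len(Y) == 0:
        grad[X.coords[:, 0], X.coords[:, 1]] += diag / len(X)
        return diag, grad
    d_xy = nearest_neighbour_distances(X, Y)
    d_yx = nearest_neighbour_distances(Y, X)
    psi_xy = spec.psi(d_xy)
    psi_yx = spec.psi(d_yx)
    value = float(psi_xy.mean() + psi_yx.mean())
    np.add.at(grad, (X.coords[:, 0], X.coords[:, 1]), psi_xy / len(X))
    np.add.at(grad, (Y.coords[:, 0], Y.coords[:, 1]), -psi_yx / len(Y))
    return value, grad
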