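"""Synthetic membrane phantoms with EM-like topology and controlled errors.

Real EM membrane ground truth is a mosaic of closed cells bounded by thin
connected curves.  The generator emulates exactly that: a Voronoi mosaic of
``n_cells`` random sites whose inter-cell boundaries form an 8-connected
membrane network (cells are 4-connected background components), dilated to a
requested thickness.  Controlled perturbations mirror the error taxonomy
that matters perceptually:

* ``dilate``     — thickness change (perceptually harmless);
* ``shift``      — small rigid misalignment (perceptually harmless);
* ``delete_edges`` — missing membrane branches (structural damage);
* ``add_spurs``  — spurious short branches (structural damage).

Everything is deterministic per seed.  ``make_trials`` builds the synthetic
stand-in for the human forced-choice experiment: each trial pairs a tolerated
perturbation (A) against a structural one (B), with simulated subject votes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core_io import BinaryMask, ProbMap, write_raster
from .consistency import PreferenceTrial
from .skeleton import PointSet

__all__ = [
    "MembranePhantom",
    "generate_phantom",
    "perturb",
    "make_trials",
    "render_image",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class MembranePhantom:
    """A synthetic membrane mosaic: ground-truth mask plus its thin skeleton."""

    seed: int
    frame: tuple[int, int]
    n_cells: int
    thickness: int
    gt: BinaryMask
    skeleton: PointSet


def _disk(radius: int) -> np.ndarray:
    if radius < 1:
        return np.ones((1, 1), dtype=bool)
    r = np.arange(-radius, radius + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius**2


def _dilate_to_thickness(thin: np.ndarray, thickness: int) -> np.ndarray:
    # disk radius (t-1)//2: exact for odd thickness, even t rounds down to t-1
    radius = (thickness - 1) // 2
    if radius == 0:
        return thin.copy()
    return ndimage.binary_dilation(thin, structure=_disk(radius))


def _sample_sites(rng: np.random.Generator, frame: tuple[int, int],
                  n_cells: int, min_sep: float) -> np.ndarray:
    h, w = frame
    for _ in range(200):
        sites = np.column_stack([rng.integers(0, h, n_cells), rng.integers(0, w, n_cells)])
        if len(np.unique(sites, axis=0)) < n_cells:
            continue
        d = np.sqrt(((sites[:, None, :] - sites[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() >= min_sep:
            return sites
    raise ValueError(f"could not place {n_cells} sites at separation {min_sep} in frame {frame}")


def generate_phantom(seed: int, frame: tuple[int, int] = (96, 96),
                     n_cells: int = 5, thickness: int = 3) -> MembranePhantom:
    """Voronoi membrane mosaic: label pixels by nearest site, mark boundaries.

    A pixel joins the membrane when its label differs from its right or lower
    neighbour, yielding a 1-pixel 8-connected boundary network whose
    complement has exactly ``n_cells`` 4-connected cell regions; the network
    is then dilated to the requested thickness.  Deterministic per seed.
    """
    h, w = frame
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if h * w < 16 * n_cells:
        raise ValueError(f"frame {frame} too small for {n_cells} cells (>= 16 px per cell)")
    rng = np.random.default_rng(seed)
    min_sep = max(4.0, 3.0 * thickness)
    sites = _sample_sites(rng, frame, n_cells, min_sep)
    rows, cols = np.mgrid[0:h, 0:w]
    pixels = np.column_stack([rows.ravel(), cols.ravel()])
    _, labels = cKDTree(sites.astype(float)).query(pixels.astype(float), k=1)
    labels = labels.reshape(h, w)

    thin = np.zeros(frame, dtype=bool)
    thin[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    thin[:-1, :] |= labels[:-1, :] != labels[1:, :]
    gt = BinaryMask(_dilate_to_thickness(thin, thickness).astype(np.uint8))
    return MembranePhantom(
        seed=seed, frame=frame, n_cells=n_cells, thickness=thickness,
        gt=gt, skeleton=PointSet(np.argwhere(thin), frame),
    )


def _junctions(skel: np.ndarray) -> np.ndarray:
    """Branch points of a thin curve: crossing number >= 3.

    The crossing number (0->1 transitions around the 8-neighbour ring) counts
    the distinct curve arcs meeting at a pixel; staircase pixels on a smooth
    8-connected curve have 2 arcs, true junctions 3 or more.
    """
    padded = np.pad(skel.astype(np.int8), 1)
    ring = [
        padded[:-2, 1:-1], padded[:-2, 2:], padded[1:-1, 2:], padded[2:, 2:],
        padded[2:, 1:-1], padded[2:, :-2], padded[1:-1, :-2], padded[:-2, :-2],
    ]
    ring.append(ring[0])
    crossings = sum((ring[i] == 0) & (ring[i + 1] == 1) for i in range(8))
    return skel & (crossings >= 3)


def perturb(phantom: MembranePhantom, kind: str, seed: int = 0, **params) -> BinaryMask:
    """Apply one named perturbation to a phantom; deterministic per seed.

    ``dilate(r)`` thickens the membrane; ``shift(dr, dc)`` translates the
    whole mask (zero fill at the border); ``delete_edges(fraction)`` removes
    that fraction of skeleton branches (segments between junctions) and
    re-dilates; ``add_spurs(k, length)`` attaches k short random branches.
    """
    rng = np.random.default_rng(seed)
    grid = phantom.gt.grid

    if kind == "dilate":
        r = int(params.get("r", 1))
        if r < 0:
            raise ValueError("dilate radius must be >= 0")
        if r == 0:
            return BinaryMask(grid.copy())
        return BinaryMask(ndimage.binary_dilation(grid, structure=_disk(r)).astype(np.uint8))

    if kind == "shift":
        dr, dc = int(params.get("dr", 0)), int(params.get("dc", 0))
        out = np.zeros_like(grid)
        h, w = grid.shape
        src_r = slice(max(0, -dr), min(h, h - dr))
        src_c = slice(max(0, -dc), min(w, w - dc))
        dst_r = slice(max(0, dr), min(h, h + dr))
        dst_c = slice(max(0, dc), min(w, w + dc))
        if src_r.start >= src_r.stop or src_c.start >= src_c.stop:
            raise ValueError(f"shift ({dr}, {dc}) moves the mask fully out of frame")
        out[dst_r, dst_c] = grid[src_r, src_c]
        if grid.any() and not out.any():
            raise ValueError(f"shift ({dr}, {dc}) moved all foreground out of frame")
        return BinaryMask(out)

    if kind == "delete_edges":
        # fraction = share of membrane length removed: whole branches (curve
        # segments between junctions) are dropped, largest-damage-first in a
        # random order, until at least that share of skeleton pixels is gone
        fraction = float(params.get("fraction", 0.3))
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if fraction >= 1.0:
            return BinaryMask(np.zeros_like(grid))
        if fraction == 0.0:
            return BinaryMask(grid.copy())
        from .skeleton import zhang_suen_thin

        skel = zhang_suen_thin(phantom.skeleton.to_mask()).grid.astype(bool)
        junctions = _junctions(skel)
        branches, n_branches = ndimage.label(skel & ~junctions, structure=_EIGHT)
        if n_branches == 0:
            return BinaryMask(np.zeros_like(grid))
        sizes = np.bincount(branches.ravel())[1:]
        order = rng.permutation(np.arange(1, n_branches + 1))
        target = fraction * skel.sum()
        removed = 0
        doomed = []
        for bid in order:
            doomed.append(bid)
            removed += sizes[bid - 1]
            if removed >= target:
                break
        kept = skel & ~np.isin(branches, doomed)
        return BinaryMask(_dilate_to_thickness(kept, phantom.thickness).astype(np.uint8))

    if kind == "add_spurs":
        k = int(params.get("k", 3))
        length = int(params.get("length", 7))
        skel = phantom.skeleton.to_mask().grid.astype(bool)
        coords = phantom.skeleton.coords
        out = skel.copy()
        h, w = skel.shape
        dirs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
        for _ in range(k):
            r, c = coords[rng.integers(len(coords))]
            dr, dc = dirs[rng.integers(8)]
            for step in range(1, length + 1):
                rr, cc = int(r + dr * step), int(c + dc * step)
                if not (0 <= rr < h and 0 <= cc < w):
                    break
                out[rr, cc] = True
        return BinaryMask(_dilate_to_thickness(out, phantom.thickness).astype(np.uint8))

    raise ValueError(f"unknown perturbation kind: {kind!r}")


#: shifts with Euclidean norm in (0, 3]: the misalignments humans forgive
_TOLERATED_SHIFTS = [
    (dr, dc)
    for dr in range(-3, 4)
    for dc in range(-3, 4)
    if 0 < dr * dr + dc * dc <= 9
]


def make_trials(n: int, seed: int = 0, frame: tuple[int, int] = (96, 96),
                n_cells: int = 5, thickness: int = 3,
                reliability: float = 0.9, n_subjects: int = 20,
                out_dir: str | Path | None = None,
                ) -> tuple[list[PreferenceTrial], list[str]]:
    """Build forced-choice trials with a known correct answer.

    Per trial: the ground truth is a fresh phantom; candidate A carries a
    tolerated perturbation (shift of norm <= 3 px, half the time also a 1-px
    dilation); candidate B carries structural damage (20-40% of branches
    deleted).  The oracle answer is always 'A'.  Each of ``n_subjects``
    simulated observers votes for the oracle side independently with
    probability ``reliability``.  Returns (trials, oracle answers); with
    ``out_dir`` the masks are written as PNGs and trials reference the files.
    """
    if n < 1:
        raise ValueError("need n >= 1 trials")
    rng = np.random.default_rng(seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    trials: list[PreferenceTrial] = []
    oracle: list[str] = []
    for i in range(n):
        phantom = generate_phantom(int(rng.integers(2**31)), frame, n_cells, thickness)
        dr, dc = _TOLERATED_SHIFTS[rng.integers(len(_TOLERATED_SHIFTS))]
        pred_a = perturb(phantom, "shift", dr=dr, dc=dc)
        if rng.random() < 0.5:
            pred_a = BinaryMask(
                ndimage.binary_dilation(pred_a.grid, structure=_disk(1)).astype(np.uint8))
        fraction = float(rng.uniform(0.2, 0.4))
        pred_b = perturb(phantom, "delete_edges", seed=int(rng.integers(2**31)),
                         fraction=fraction)
        votes_a = int(rng.binomial(n_subjects, reliability))
        votes_b = n_subjects - votes_a

        trial_id = f"trial_{i:04d}"
        if out is not None:
            paths = {}
            for name, mask in [("gt", phantom.gt), ("pred_a", pred_a), ("pred_b", pred_b)]:
                p = out / f"{trial_id}_{name}.png"
                write_raster(mask, p)
                paths[name] = p.name
            trials.append(PreferenceTrial(trial_id, out / paths["gt"], out / paths["pred_a"],
                                          out / paths["pred_b"], votes_a, votes_b))
        else:
            trials.append(PreferenceTrial(trial_id, phantom.gt, pred_a, pred_b, votes_a, votes_b))
        oracle.append("A")
    return trials, oracle


def render_image(phantom: MembranePhantom, seed: int = 0, noise_sd: float = 0.05) -> ProbMap:
    """Grayscale rendering for training: bright membrane on a dark background.

    Intensities are ground-truth-correlated Gaussians (membrane ~0.85,
    background ~0.15, sd ``noise_sd``), clipped to [0, 1].  This captures the
    intensity contrast a segmentation network exploits but none of the
    texture, staining variation, or out-of-plane structure of real EM data.
    """
    rng = np.random.default_rng(seed)
    base = 0.15 + 0.7 * phantom.gt.grid.astype(np.float64)
    noisy = base + rng.normal(0.0, noise_sd, size=base.shape)
    return ProbMap(np.clip(noisy, 0.0, 1.0))
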