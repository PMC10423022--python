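"""Desk-scale global-local segmentation pipeline.

Two branches segment the same frame at two scales: the *global* branch sees
the full image, the *local* branch sees N same-size crops.  Both branches
run one shared-weight u-shaped encoder-decoder (a small fully-convolutional
network: conv -> pool -> conv -> upsample -> skip-concat -> conv -> 1x1
head -> softmax), so a single parameter set serves both scales.  Training
optimizes

    L = L_pixel + lambda1 * L_phd + lambda2 * L_sim

with the coarse-to-fine schedule of :mod:`phdseg.losses`; prediction fuses
the global probability map with the stitched local maps by pixel-wise
averaging and binarizes at 0.5.

The implementation is pure numpy with manual backprop (im2col convolutions,
Adam), which keeps the full training loop bit-reproducible under a fixed
seed on any CPU.  The default backbone has ~4k parameters — deliberately
tiny: the pipeline exists to exercise the loss machinery and the global-local
architecture at desk scale, not to compete on real EM benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import BinaryMask, ProbMap, binarize
from .losses import (
    ClassWeighting,
    LossSchedule,
    phd_pointset_grad,
    pixel_loss_grad,
    schedule_weights,
)
from .phd import LOSS_TAU_DEFAULT, ToleranceSpec, nearest_neighbour_distances
from .skeleton import PointSet, mask_to_pointset, soft_skeleton

__all__ = [
    "PatchGrid",
    "BranchModel",
    "TrainConfig",
    "crop_patches",
    "stitch",
    "fuse",
    "train",
    "predict",
]


# ---------------------------------------------------------------------------
# patch grid


@dataclass(frozen=True)
class PatchGrid:
    """N same-size patches anchored at (row, col) offsets within a frame.

    The default construction (:meth:`regular`) tiles the frame exactly with
    non-overlapping patches, for which stitch(crop(x)) == x bit-exactly.
    Explicit offsets may overlap; stitching then averages overlapped pixels.
    """

    frame: tuple[int, int]
    patch_size: tuple[int, int]
    offsets: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        h, w = self.frame
        ph, pw = self.patch_size
        if ph < 1 or pw < 1 or ph > h or pw > w:
            raise ValueError(f"patch size {self.patch_size} incompatible with frame {self.frame}")
        cover = np.zeros(self.frame, dtype=bool)
        for r, c in self.offsets:
            if r < 0 or c < 0 or r + ph > h or c + pw > w:
                raise ValueError(f"patch at ({r}, {c}) exceeds the frame")
            cover[r:r + ph, c:c + pw] = True
        if not cover.all():
            raise ValueError("patches must cover every pixel of the frame")
        object.__setattr__(self, "frame", tuple(self.frame))
        object.__setattr__(self, "patch_size", tuple(self.patch_size))
        object.__setattr__(self, "offsets", tuple(tuple(o) for o in self.offsets))

    @property
    def n(self) -> int:
        return len(self.offsets)

    @staticmethod
    def regular(frame: tuple[int, int], rows: int = 2, cols: int = 2) -> "PatchGrid":
        """Non-overlapping rows x cols tiling; the frame must divide evenly."""
        h, w = frame
        if h % rows or w % cols:
            raise ValueError(f"frame {frame} not divisible into {rows}x{cols} patches")
        ph, pw = h // rows, w // cols
        offsets = [(i * ph, j * pw) for i in range(rows) for j in range(cols)]
        return PatchGrid(frame=(h, w), patch_size=(ph, pw), offsets=tuple(offsets))


def crop_patches(image: np.ndarray, grid: PatchGrid) -> list[np.ndarray]:
    """Crop the N grid patches out of a 2-D image, in grid order."""
    if image.shape != grid.frame:
        raise ValueError(f"image shape {image.shape} does not match grid frame {grid.frame}")
    ph, pw = grid.patch_size
    return [image[r:r + ph, c:c + pw].copy() for r, c in grid.offsets]


def stitch(patches: Sequence[np.ndarray], grid: PatchGrid) -> np.ndarray:
    """Reassemble patches into the frame; overlapped pixels are averaged."""
    if len(patches) != grid.n:
        raise ValueError(f"expected {grid.n} patches, got {len(patches)}")
    ph, pw = grid.patch_size
    acc = np.zeros(grid.frame, dtype=np.float64)
    cnt = np.zeros(grid.frame, dtype=np.float64)
    for patch, (r, c) in zip(patches, grid.offsets):
        if patch.shape != (ph, pw):
            raise ValueError(f"patch shape {patch.shape} != {grid.patch_size}")
        acc[r:r + ph, c:c + pw] += patch
        cnt[r:r + ph, c:c + pw] += 1.0
    out = acc / cnt
    if all(np.issubdtype(np.asarray(p).dtype, np.integer) for p in patches) and (cnt == 1).all():
        return out.astype(patches[0].dtype)
    return out


def fuse(global_prob: ProbMap, stitched_local_prob: ProbMap) -> ProbMap:
    """Average-pool fusion of the two branch probability maps."""
    if global_prob.shape != stitched_local_prob.shape:
        raise ValueError("probability maps must share a shape")
    return ProbMap(0.5 * (global_prob.grid + stitched_local_prob.grid))


# ---------------------------------------------------------------------------
# numpy layers


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    f, cin, k, _ = w.shape
    c, h, wid = x.shape
    p = k // 2
    padded = np.pad(x, ((0, 0), (p, p), (p, p)))
    sw = np.lib.stride_tricks.sliding_window_view(padded, (k, k), axis=(1, 2))
    cols = sw.transpose(1, 2, 0, 3, 4).reshape(h * wid, c * k * k)
    wm = w.reshape(f, c * k * k)
    out = (cols @ wm.T).T.reshape(f, h, wid) + b[:, None, None]
    return out, (cols, x.shape, w)


def _conv_backward(dout: np.ndarray, cache):
    cols, x_shape, w = cache
    f, cin, k, _ = w.shape
    c, h, wid = x_shape
    p = k // 2
    dout_mat = dout.reshape(f, h * wid).T
    dw = (dout_mat.T @ cols).reshape(w.shape)
    db = dout.sum(axis=(1, 2))
    dcols = (dout_mat @ w.reshape(f, c * k * k)).reshape(h, wid, c, k, k)
    dpad = np.zeros((c, h + 2 * p, wid + 2 * p))
    for i in range(k):
        for j in range(k):
            dpad[:, i:i + h, j:j + wid] += dcols[:, :, :, i, j].transpose(2, 0, 1)
    return dpad[:, p:p + h, p:p + wid], dw, db


def _avgpool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def _avgpool2_back(d: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(d, 2, axis=1), 2, axis=2) / 4.0


def _upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _upsample2_back(d: np.ndarray) -> np.ndarray:
    c, h, w = d.shape
    return d.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


def _softmax2(z: np.ndarray) -> np.ndarray:
    zs = z - z.max(axis=0, keepdims=True)
    e = np.exp(zs)
    return e / e.sum(axis=0, keepdims=True)


def _softmax2_back(s: np.ndarray, ds: np.ndarray) -> np.ndarray:
    inner = (ds * s).sum(axis=0, keepdims=True)
    return s * (ds - inner)


# ---------------------------------------------------------------------------
# model


class BranchModel:
    """Shared-weight u-shaped encoder-decoder over single-channel images.

    conv3x3(1->c) ReLU -> avgpool2 -> conv3x3(c->2c) ReLU -> upsample2 ->
    concat skip -> conv3x3(3c->c) ReLU -> conv1x1(c->2) -> softmax.
    Fully convolutional, so the same parameters segment the full frame
    (global branch) and the crops (local branch); input sides must be even.
    """

    def __init__(self, channels: int = 8, seed: int = 0):
        self.channels = channels
        rng = np.random.default_rng(seed)
        c = channels

        def he(shape):
            fan_in = shape[1] * shape[2] * shape[3]
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params: dict[str, np.ndarray] = {
            "w1": he((c, 1, 3, 3)), "b1": np.zeros(c),
            "w2": he((2 * c, c, 3, 3)), "b2": np.zeros(2 * c),
            "w3": he((c, 3 * c, 3, 3)), "b3": np.zeros(c),
            "w4": he((2, c, 1, 1)), "b4": np.zeros(2),
        }

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def forward(self, image: np.ndarray):
        """Per-class probabilities (2, H, W) plus the backprop cache."""
        if image.ndim != 2 or image.shape[0] % 2 or image.shape[1] % 2:
            raise ValueError(f"expected a 2-D image with even sides, got {image.shape}")
        p = self.params
        x = image[None].astype(np.float64)
        a1, c1 = _conv_forward(x, p["w1"], p["b1"])
        r1 = np.maximum(a1, 0.0)
        pooled = _avgpool2(r1)
        a2, c2 = _conv_forward(pooled, p["w2"], p["b2"])
        r2 = np.maximum(a2, 0.0)
        up = _upsample2(r2)
        cat = np.concatenate([r1, up], axis=0)
        a3, c3 = _conv_forward(cat, p["w3"], p["b3"])
        r3 = np.maximum(a3, 0.0)
        z, c4 = _conv_forward(r3, p["w4"], p["b4"])
        s = _softmax2(z)
        cache = (c1, a1, c2, a2, c3, a3, c4, s)
        return s, cache

    def backward(self, cache, ds: np.ndarray) -> dict[str, np.ndarray]:
        """Parameter gradients from dL/d(probabilities)."""
        c1, a1, c2, a2, c3, a3, c4, s = cache
        dz = _softmax2_back(s, ds)
        dr3, dw4, db4 = _conv_backward(dz, c4)
        da3 = dr3 * (a3 > 0)
        dcat, dw3, db3 = _conv_backward(da3, c3)
        c = self.channels
        dr1_skip, dup = dcat[:c], dcat[c:]
        dr2 = _upsample2_back(dup)
        da2 = dr2 * (a2 > 0)
        dpooled, dw2, db2 = _conv_backward(da2, c2)
        dr1 = dr1_skip + _avgpool2_back(dpooled)
        da1 = dr1 * (a1 > 0)
        _, dw1, db1 = _conv_backward(da1, c1)
        return {"w1": dw1, "b1": db1, "w2": dw2, "b2": db2,
                "w3": dw3, "b3": db3, "w4": dw4, "b4": db4}

    def predict_prob(self, image: np.ndarray) -> ProbMap:
        s, _ = self.forward(image)
        return ProbMap(s[1])


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mh = self.m[k] / (1 - self.beta1**self.t)
            vh = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    """Configuration for the coarse-to-fine training loop.

    ``branches`` selects the architecture ablation ('global', 'local' or
    'both'); ``use_phd`` / ``use_sim`` select the loss ablation on top of the
    always-on pixel loss.  ``pixel_branch_mode`` averages ('mean', default)
    or sums the two branch pixel losses.  ``steps_per_epoch`` gradient
    updates are taken per epoch over the (tiny, desk-scale) training set.
    """

    epochs: int = 20
    lr: float = 0.02
    seed: int = 0
    channels: int = 8
    grid_rows: int = 2
    grid_cols: int = 2
    steps_per_epoch: int = 5
    tau_loss: float = LOSS_TAU_DEFAULT
    threshold: float = 0.5
    schedule: LossSchedule = field(default_factory=LossSchedule)
    use_phd: bool = True
    use_sim: bool = True
    branches: str = "both"  # 'global' | 'local' | 'both'
    pixel_branch_mode: str = "mean"  # 'mean' | 'sum'

    def __post_init__(self) -> None:
        if self.branches not in {"global", "local", "both"}:
            raise ValueError("branches must be 'global', 'local' or 'both'")
        if self.pixel_branch_mode not in {"mean", "sum"}:
            raise ValueError("pixel_branch_mode must be 'mean' or 'sum'")


def _as_image(img) -> np.ndarray:
    if isinstance(img, ProbMap):
        return img.grid
    return np.asarray(img, dtype=np.float64)


def _sim_value_and_grads(Xg: PointSet, local_sets: list[PointSet], grid: PatchGrid,
                         spec: ToleranceSpec, frame: tuple[int, int]):
    """L_sim plus straight-through gradients for the global plane and each patch."""
    dg = np.zeros(frame)
    dl = [np.zeros(grid.patch_size) for _ in range(grid.n)]
    shifted = [ps.translated(r, c, frame) for ps, (r, c) in zip(local_sets, grid.offsets)]
    Xhat = PointSet.union(shifted, frame)
    diag = float(np.hypot(*frame))
    if len(Xg) == 0 and len(Xhat) == 0:
        return 0.0, dg, dl
    if len(Xhat) == 0:
        dg[Xg.coords[:, 0], Xg.coords[:, 1]] += diag / len(Xg)
        return diag, dg, dl
    if len(Xg) == 0:
        for i, ps in enumerate(local_sets):
            if len(ps):
                dl[i][ps.coords[:, 0], ps.coords[:, 1]] += diag / len(Xhat)
        return diag, dg, dl
    d_g = nearest_neighbour_distances(Xg, Xhat)
    psi_g = spec.psi(d_g)
    np.add.at(dg, (Xg.coords[:, 0], Xg.coords[:, 1]), psi_g / len(Xg))
    d_hat = nearest_neighbour_distances(Xhat, Xg)
    psi_hat = spec.psi(d_hat)
    value = float(psi_g.mean() + psi_hat.mean())
    # route each stitched point's gradient back to the patch that produced it
    plane = np.zeros(frame)
    np.add.at(plane, (Xhat.coords[:, 0], Xhat.coords[:, 1]), psi_hat / len(Xhat))
    ph, pw = grid.patch_size
    for i, (r, c) in enumerate(grid.offsets):
        ps = local_sets[i]
        if len(ps):
            rows, cols = ps.coords[:, 0], ps.coords[:, 1]
            dl[i][rows, cols] += plane[rows + r, cols + c]
    return value, dg, dl


def train(pairs: Sequence[tuple], config: TrainConfig | None = None
          ) -> tuple[BranchModel, list[dict[str, float]]]:
    """Train the two-branch model; returns (model, per-epoch loss history).

    Each history entry records the epoch's mean pixel / PHD / similarity loss
    components, the schedule weights, and the weighted total.  The run is
    fully deterministic for a fixed ``config.seed``.
    """
    config = config if config is not None else TrainConfig()
    if not pairs:
        raise ValueError("need at least one training pair")
    images = [_as_image(img) for img, _ in pairs]
    gts: list[BinaryMask] = [gt for _, gt in pairs]
    frame = gts[0].shape
    grid = PatchGrid.regular(frame, config.grid_rows, config.grid_cols)
    weighting = ClassWeighting.from_masks(gts)
    spec = ToleranceSpec(tau=config.tau_loss)
    model = BranchModel(channels=config.channels, seed=config.seed)
    opt = _Adam(model.params, config.lr)
    use_global = config.branches in {"global", "both"}
    use_local = config.branches in {"local", "both"}
    use_sim = config.use_sim and use_global and use_local

    gt_patch_masks = [[BinaryMask(p) for p in crop_patches(g.grid, grid)] for g in gts]
    gt_skels = [mask_to_pointset(g, skeletonize=True) for g in gts]
    gt_patch_skels = [[mask_to_pointset(p, skeletonize=True) for p in patches]
                      for patches in gt_patch_masks]

    history: list[dict[str, float]] = []
    for epoch in range(config.epochs):
        lam1, lam2 = schedule_weights(epoch, config.schedule)
        if not config.use_phd:
            lam1 = 0.0
        if not use_sim:
            lam2 = 0.0
        ep_pixel, ep_phd, ep_sim, n_obs = 0.0, 0.0, 0.0, 0
        for _ in range(config.steps_per_epoch):
            for img, gt, gpatches, gskel, gpskels in zip(
                    images, gts, gt_patch_masks, gt_skels, gt_patch_skels):
                l_pixel, l_phd, l_sim, grads = _pair_step(
                    model, img, gt, grid, gpatches, gskel, gpskels, weighting,
                    spec, config, lam1, lam2, use_global, use_local, use_sim)
                if not np.isfinite(l_pixel + l_phd + l_sim):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                opt.step(model.params, grads)
                ep_pixel += l_pixel
                ep_phd += l_phd
                ep_sim += l_sim
                n_obs += 1
        entry = {
            "epoch": float(epoch),
            "pixel": ep_pixel / n_obs,
            "phd": ep_phd / n_obs,
            "sim": ep_sim / n_obs,
            "lambda1": lam1,
            "lambda2": lam2,
        }
        entry["total"] = entry["pixel"] + lam1 * entry["phd"] + lam2 * entry["sim"]
        history.append(entry)
    return model, history


def _pair_step(model, img, gt, grid, gt_patches, gt_skel, gt_patch_skels, weighting,
               spec, config, lam1, lam2, use_global, use_local, use_sim):
    """Forward both branches on one pair, return losses and parameter grads."""
    frame = gt.shape
    grads = {k: np.zeros_like(v) for k, v in model.params.items()}
    pixel_scale = 0.5 if (use_global and use_local and config.pixel_branch_mode == "mean") else 1.0

    sg = cache_g = None
    local_s, local_caches = [], []
    if use_global:
        sg, cache_g = model.forward(img)
    if use_local:
        for patch in crop_patches(img, grid):
            s, cache = model.forward(patch)
            local_s.append(s)
            local_caches.append(cache)

    l_pixel = 0.0
    ds_g = np.zeros((2,) + frame) if use_global else None
    ds_l = [np.zeros((2,) + grid.patch_size) for _ in local_s]
    if use_global:
        lp, dlp = pixel_loss_grad(sg, gt, weighting)
        l_pixel += pixel_scale * lp
        ds_g += pixel_scale * dlp
    if use_local:
        n = grid.n
        for i, (s, gpatch) in enumerate(zip(local_s, gt_patches)):
            lp, dlp = pixel_loss_grad(s, gpatch, weighting)
            l_pixel += pixel_scale * lp / n
            ds_l[i] += (pixel_scale / n) * dlp

    # skeletons are needed by both structural losses; compute once when active
    l_phd = l_sim = 0.0
    if lam1 > 0.0 or lam2 > 0.0:
        Xg = (soft_skeleton(ProbMap(sg[1]), config.threshold) if use_global
              else PointSet(np.empty((0, 2), dtype=np.int64), frame))
        local_skels = [soft_skeleton(ProbMap(s[1]), config.threshold) for s in local_s]

        if lam1 > 0.0:
            if use_global:
                v, gplane = phd_pointset_grad(Xg, gt_skel, spec, frame)
                l_phd += v
                ds_g[1] += lam1 * gplane
            if use_local:
                used = []
                patch_grads = []
                for i, (Xl, Yl) in enumerate(zip(local_skels, gt_patch_skels)):
                    if len(Yl) == 0:
                        continue
                    v, gplane = phd_pointset_grad(Xl, Yl, spec, grid.patch_size)
                    used.append(v)
                    patch_grads.append((i, gplane))
                if used:
                    l_phd += float(np.mean(used))
                    for i, gplane in patch_grads:
                        ds_l[i][1] += (lam1 / len(used)) * gplane

        if lam2 > 0.0 and use_sim:
            v, dg, dl = _sim_value_and_grads(Xg, local_skels, grid, spec, frame)
            l_sim = v
            ds_g[1] += lam2 * dg
            for i, gplane in enumerate(dl):
                ds_l[i][1] += lam2 * gplane

    if use_global:
        for k, v in model.backward(cache_g, ds_g).items():
            grads[k] += v
    for cache, ds in zip(local_caches, ds_l):
        for k, v in model.backward(cache, ds).items():
            grads[k] += v
    return l_pixel, l_phd, l_sim, grads


def predict(model: BranchModel, image, grid: PatchGrid | None = None,
            branches: str = "both", threshold: float = 0.5
            ) -> tuple[ProbMap, BinaryMask]:
    """Segment an image: global + stitched local branches, fused, binarized."""
    img = _as_image(image)
    if grid is None:
        grid = PatchGrid.regular(img.shape)
    if branches == "global":
        prob = model.predict_prob(img)
    else:
        locals_prob = [model.predict_prob(p).grid for p in crop_patches(img, grid)]
        stitched = ProbMap(stitch(locals_prob, grid))
        if branches == "local":
            prob = stitched
        else:
            prob = fuse(model.predict_prob(img), stitched)
    return prob, binarize(prob, threshold)
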