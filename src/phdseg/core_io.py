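"""Raster I/O and the shared mask / probability-map data model.

Conventions used by every module in the package:

* arrays are 2-D, row-major, origin at the top-left; coordinates are
  ``(row, col)``, 0-based;
* binary masks hold ``{0, 1}`` with foreground ``1`` = membrane;
* probability maps hold reals in ``[0, 1]`` (per-pixel membrane probability).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = ["BinaryMask", "ProbMap", "read_raster", "write_raster", "binarize"]


@dataclass(frozen=True)
class BinaryMask:
    """A 2-D {0,1} segmentation mask; foreground (1) marks membrane pixels."""

    grid: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2 or grid.shape[0] < 1 or grid.shape[1] < 1:
            raise ValueError(f"mask must be 2-D and non-empty, got shape {grid.shape}")
        grid = grid.astype(np.uint8, copy=False)
        if not np.isin(grid, (0, 1)).all():
            raise ValueError("mask values must be exactly {0, 1}")
        object.__setattr__(self, "grid", grid)

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def inverted(self) -> "BinaryMask":
        """Flip polarity (for datasets where membrane is stored as 0)."""
        return BinaryMask(1 - self.grid)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BinaryMask) and np.array_equal(self.grid, other.grid)


@dataclass(frozen=True)
class ProbMap:
    """A 2-D map of per-pixel membrane probabilities in [0, 1]."""

    grid: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.float64)
        if grid.ndim != 2 or grid.shape[0] < 1 or grid.shape[1] < 1:
            raise ValueError(f"probability map must be 2-D and non-empty, got shape {grid.shape}")
        if not ((grid >= 0.0) & (grid <= 1.0)).all():
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "grid", grid)

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def _load_array(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as img:
            arr = np.asarray(img)
    return arr


def read_raster(path: str | Path) -> BinaryMask | ProbMap:
    """Read a single-channel PNG or TIFF raster.

    Integer rasters with at most two distinct values are interpreted as
    binary masks (maximum value -> 1).  Anything else is rescaled to a
    probability map: integer dtypes by their dtype range, floating rasters
    are required to already lie in [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster not found: {path}")
    arr = _load_array(path)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel raster, got shape {arr.shape}: {path}")

    if np.issubdtype(arr.dtype, np.integer):
        values = set(np.unique(arr).tolist())
        full = np.iinfo(arr.dtype).max
        # Binary iff values use only {0, dtype-max} (or a raw {0,1} labelling);
        # a two-valued but mid-range raster (e.g. constant 128) stays a ProbMap
        # so that quantized probability maps round-trip as probabilities.
        if values <= {0, full} or values <= {0, 1}:
            return BinaryMask((arr > 0).astype(np.uint8))
        return ProbMap(arr.astype(np.float64) / float(full))
    if np.issubdtype(arr.dtype, np.floating):
        return ProbMap(arr.astype(np.float64))
    raise ValueError(f"unsupported raster dtype {arr.dtype}: {path}")


def write_raster(obj: BinaryMask | ProbMap, path: str | Path) -> None:
    """Write a mask or probability map as an 8-bit single-channel raster.

    Binary masks round-trip exactly ({0,1} -> {0,255}); probability maps are
    quantized to 8 bits (error at most 1/255 per pixel on round-trip).
    """
    path = Path(path)
    if isinstance(obj, BinaryMask):
        arr = (obj.grid * 255).astype(np.uint8)
    elif isinstance(obj, ProbMap):
        arr = np.rint(obj.grid * 255.0).astype(np.uint8)
    else:
        raise TypeError(f"expected BinaryMask or ProbMap, got {type(obj).__name__}")

    suffix = path.suffix.lower()
    try:
        if suffix in {".tif", ".tiff"}:
            tifffile.imwrite(path, arr)
        else:
            Image.fromarray(arr, mode="L").save(path)
    except OSError as exc:  # unwritable path
        raise IOError(f"cannot write raster to {path}: {exc}") from exc


def binarize(p: ProbMap, threshold: float = 0.5) -> BinaryMask:
    """Threshold a probability map: pixel -> 1 iff value > threshold (strict).

    The strict inequality is deliberate and fixed so results are bit-exact;
    a constant map equal to the threshold binarizes to all-background.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return BinaryMask((p.grid > threshold).astype(np.uint8))
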