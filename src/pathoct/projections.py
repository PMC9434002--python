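"""En-face Z-projection statistics, B-scan extraction and image export.

A volume is "flattened" along depth with one of five statistics —
maximum, sum, average, median, standard deviation — each highlighting
different features of a specimen (topology for maximum; internal contrast
for median/average/std).  Projections operate on linear magnitude by
default; the standard deviation is the population (ddof = 0) value, a
descriptive statistic of the full depth window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import tifffile
from PIL import Image

from .mosaic import MosaicVolume
from .recon import OCTVolume

STATISTICS = ("maximum", "sum", "average", "median", "std")
_ALIASES = {
    "max": "maximum",
    "avg": "average",
    "mean": "average",
    "stdev": "std",
}


@dataclass
class ProjectionImage:
    values: np.ndarray  # [Y][X]
    statistic: str
    depth_window: Tuple[int, int]
    mm_per_pixel: Tuple[float, float]  # (y, x)
    transform: str = "none"  # none | log | percentile-rescale
    metadata: dict = field(default_factory=dict)


VolumeLike = Union[OCTVolume, MosaicVolume, np.ndarray]


def _as_array(volume: VolumeLike) -> Tuple[np.ndarray, Tuple[float, float]]:
    if isinstance(volume, (OCTVolume, MosaicVolume)):
        return volume.magnitude, (volume.pitch_y_mm, volume.pitch_x_mm)
    arr = np.asarray(volume)
    if arr.ndim != 3:
        raise ValueError("expected a [Y][X][Z] volume")
    return arr, (1.0, 1.0)


def z_project(
    volume: VolumeLike,
    statistic: str = "average",
    depth_window: Optional[Tuple[int, int]] = None,
) -> ProjectionImage:
    """Per-(Y, X) statistic over a half-open depth-bin window."""
    stat = _ALIASES.get(statistic, statistic)
    if stat not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    arr, pitch = _as_array(volume)
    nz = arr.shape[2]
    lo, hi = depth_window if depth_window is not None else (0, nz)
    if not (0 <= lo < hi <= nz):
        raise ValueError(f"depth window ({lo}, {hi}) is empty or outside [0, {nz}]")
    sub = arr[:, :, lo:hi]
    if stat == "maximum":
        vals = sub.max(axis=2)
    elif stat == "sum":
        vals = sub.sum(axis=2, dtype=np.float64)
    elif stat == "average":
        vals = sub.mean(axis=2, dtype=np.float64)
    elif stat == "median":
        vals = np.median(sub, axis=2)
    else:
        vals = sub.std(axis=2, ddof=0, dtype=np.float64)
    return ProjectionImage(
        values=np.asarray(vals),
        statistic=stat,
        depth_window=(lo, hi),
        mm_per_pixel=pitch,
    )


def extract_bscan(volume: VolumeLike, axis: str = "fast", index: int = 0) -> np.ndarray:
    """One cross-sectional plane, oriented depth × lateral.

    ``fast`` slices at a fixed slow-axis (B-scan/Y) index; ``slow`` slices
    at a fixed fast-axis (A-line/X) index.
    """
    arr, _ = _as_array(volume)
    ny, nx, _ = arr.shape
    if axis == "fast":
        if not 0 <= index < ny:
            raise IndexError(f"B-scan index {index} outside [0, {ny})")
        return arr[index].T.copy()  # [Z][X]
    if axis == "slow":
        if not 0 <= index < nx:
            raise IndexError(f"A-line index {index} outside [0, {nx})")
        return arr[:, index].T.copy()  # [Z][Y]
    raise ValueError("axis must be 'fast' or 'slow'")


def rescale_to_codes(
    values: np.ndarray,
    bit_depth: int = 8,
    policy: str = "percentile",
    percentiles: Tuple[float, float] = (1.0, 99.0),
) -> np.ndarray:
    """Map image values onto integer code values for export.

    ``percentile`` (default 1–99%) clips outliers; ``minmax`` uses the full
    range.  A constant image falls back to mid-gray with a warning.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit depth must be 8 or 16")
    v = np.asarray(values, dtype=float)
    if policy == "percentile":
        lo, hi = np.percentile(v, percentiles)
    elif policy == "minmax":
        lo, hi = float(v.min()), float(v.max())
    else:
        raise ValueError("rescale policy must be 'percentile' or 'minmax'")
    max_code = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    if hi <= lo:
        warnings.warn("constant image: falling back to mid-gray", stacklevel=2)
        return np.full(v.shape, max_code // 2, dtype=dtype)
    codes = np.clip((v - lo) / (hi - lo), 0.0, 1.0) * max_code
    return np.round(codes).astype(dtype)


def export_image(
    image: Union[ProjectionImage, np.ndarray],
    path,
    bit_depth: int = 8,
    rescale: str = "percentile",
    percentiles: Tuple[float, float] = (1.0, 99.0),
) -> str:
    """Write a projection or 2-D array as PNG or TIFF (by extension).

    Integer inputs written as 16-bit TIFF without rescaling round-trip
    losslessly (``rescale='none'``).
    """
    path = str(path)
    vals = image.values if isinstance(image, ProjectionImage) else np.asarray(image)
    if rescale == "none":
        codes = vals
    else:
        codes = rescale_to_codes(vals, bit_depth, rescale, percentiles)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, codes)
    elif path.lower().endswith(".png"):
        if codes.dtype == np.uint16:
            Image.fromarray(codes, mode="I;16").save(path)
        else:
            Image.fromarray(codes.astype(np.uint8), mode="L").save(path)
    else:
        raise ValueError("unsupported image format: use .png, .tif or .tiff")
    return path


def projection_panel(
    volume: VolumeLike,
    statistics: Sequence[str] = STATISTICS,
    depth_window: Optional[Tuple[int, int]] = None,
    gap_px: int = 4,
) -> np.ndarray:
    """Side-by-side 8-bit panel of several projections of one volume."""
    tiles = []
    for stat in statistics:
        proj = z_project(volume, stat, depth_window)
        tiles.append(rescale_to_codes(proj.values, 8, "percentile"))
    h = tiles[0].shape[0]
    gap = np.zeros((h, gap_px), dtype=np.uint8)
    parts: list[np.ndarray] = []
    for i, t in enumerate(tiles):
        if i:
            parts.append(gap)
        parts.append(t)
    return np.hstack(parts)
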