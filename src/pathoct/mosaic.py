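"""Serpentine scan planning and tile mosaicking.

A cassette larger than one tile field of view is covered by a serpentine
("snake") grid: the stage visits grid-adjacent tiles, reversing direction
on every row, starting from a configurable origin corner (default
lower-right, where the specimen is placed).  Reconstructed tile volumes
are then assembled into one large-field volume.

Conventions (recorded in exported metadata): row 0 is the *bottom* row of
the grid, x increases rightward; the mosaic array is indexed [Y][X][Z]
with Y along B-scans (slow axis) and X along A-lines (fast axis).  Tiles
share the depth axis verbatim — no Z registration.

With zero overlap tiles abut exactly and no blending is applied.  With a
positive overlap two policies exist: ``crop-to-center`` (default; each
output column is taken from the tile whose grid cell center is nearest,
i.e. the overlap band is split at its midline) and ``average`` (plain mean
over contributing tiles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict

from .recon import OCTVolume

MAX_EXTENT_MM = 100.0  # scan stage covers up to 10 cm x 10 cm


class OriginCorner(str, Enum):
    lower_right = "lower_right"
    lower_left = "lower_left"
    upper_right = "upper_right"
    upper_left = "upper_left"


class TilePose(BaseModel):
    model_config = ConfigDict(frozen=True)

    row: int
    col: int
    x_mm: float  # stage position of the tile center
    y_mm: float


class ScanPlan(BaseModel):
    """Serpentine tile grid over a specimen extent."""

    model_config = ConfigDict(frozen=True)

    rows: int
    cols: int
    tile_fov_mm: Tuple[float, float]
    overlap_mm: float = 0.0
    origin: OriginCorner = OriginCorner.lower_right
    tiles: Tuple[TilePose, ...] = ()  # in serpentine visit order

    def visit_order(self) -> List[Tuple[int, int]]:
        return [(t.row, t.col) for t in self.tiles]


def plan_snake_scan(
    width_mm: float,
    height_mm: float,
    tile_fov_mm,
    overlap_mm: float = 0.0,
    origin: str | OriginCorner = OriginCorner.lower_right,
) -> ScanPlan:
    """Plan a serpentine grid covering ``width × height`` mm.

    ``rows = ⌈height/stride⌉`` and ``cols = ⌈width/stride⌉`` with
    ``stride = tile_fov − overlap`` per axis.  The visit order starts at
    the origin corner and traverses along the row first, reversing on each
    row so consecutive tiles are always grid-adjacent.
    """
    fov = (
        (float(tile_fov_mm), float(tile_fov_mm))
        if np.isscalar(tile_fov_mm)
        else (float(tile_fov_mm[0]), float(tile_fov_mm[1]))
    )
    origin = OriginCorner(origin)
    if width_mm <= 0 or height_mm <= 0:
        raise ValueError("extent must be positive")
    if width_mm > MAX_EXTENT_MM or height_mm > MAX_EXTENT_MM:
        raise ValueError(f"extent exceeds the {MAX_EXTENT_MM:.0f} mm stage travel")
    if overlap_mm < 0:
        raise ValueError("overlap must be >= 0")
    stride_x, stride_y = fov[0] - overlap_mm, fov[1] - overlap_mm
    if stride_x <= 0 or stride_y <= 0:
        raise ValueError("tile field of view must exceed the overlap")
    # tolerance guards against float ratios like 0.8/0.4 -> 2.0000000000000004
    cols = math.ceil(width_mm / stride_x - 1e-9)
    rows = math.ceil(height_mm / stride_y - 1e-9)

    row_seq = range(rows) if origin in (OriginCorner.lower_right, OriginCorner.lower_left) else range(rows - 1, -1, -1)
    start_right = origin in (OriginCorner.lower_right, OriginCorner.upper_right)
    tiles: List[TilePose] = []
    for i, r in enumerate(row_seq):
        cols_seq = range(cols - 1, -1, -1) if (start_right ^ (i % 2 == 1)) else range(cols)
        for c in cols_seq:
            tiles.append(
                TilePose(
                    row=r,
                    col=c,
                    x_mm=c * stride_x + fov[0] / 2.0,
                    y_mm=r * stride_y + fov[1] / 2.0,
                )
            )
    return ScanPlan(
        rows=rows,
        cols=cols,
        tile_fov_mm=fov,
        overlap_mm=overlap_mm,
        origin=origin,
        tiles=tuple(tiles),
    )


@dataclass
class MosaicVolume:
    """Stitched large-field volume [Y][X][Z] with per-column provenance."""

    magnitude: np.ndarray  # float32 [Y][X][Z]
    pitch_x_mm: float
    pitch_y_mm: float
    pitch_z_um: float
    provenance_map: np.ndarray  # int32 [Y][X], flat tile index row*cols+col
    metadata: dict = field(default_factory=dict)


def _overlap_pixels(plan: ScanPlan, pitch_x_mm: float, pitch_y_mm: float) -> Tuple[int, int]:
    ox = int(round(plan.overlap_mm / pitch_x_mm)) if plan.overlap_mm else 0
    oy = int(round(plan.overlap_mm / pitch_y_mm)) if plan.overlap_mm else 0
    return ox, oy


def stitch_tiles(
    volumes: Sequence[OCTVolume],
    plan: ScanPlan,
    policy: str = "crop-to-center",
) -> MosaicVolume:
    """Assemble reconstructed tiles into one mosaic per the scan plan.

    Placement depends only on each tile's (row, col) — never on the visit
    order — so reversing the serpentine origin yields an identical mosaic.
    """
    if policy not in ("crop-to-center", "average"):
        raise ValueError("policy must be 'crop-to-center' or 'average'")
    by_index: Dict[Tuple[int, int], OCTVolume] = {}
    for v in volumes:
        by_index[tuple(v.tile_index)] = v
    missing = [
        (r, c)
        for r in range(plan.rows)
        for c in range(plan.cols)
        if (r, c) not in by_index
    ]
    if missing:
        raise ValueError(f"missing tiles for plan positions: {missing}")

    first = by_index[(0, 0)]
    nb, na, nz = first.shape
    for v in by_index.values():
        if v.shape != (nb, na, nz):
            raise ValueError("all tile volumes must share one shape")
        if not np.isclose(v.pitch_x_mm, first.pitch_x_mm) or not np.isclose(
            v.pitch_y_mm, first.pitch_y_mm
        ):
            raise ValueError("all tile volumes must share one lateral pitch")

    ox, oy = _overlap_pixels(plan, first.pitch_x_mm, first.pitch_y_mm)
    if ox >= na or oy >= nb:
        raise ValueError("overlap is as large as the tile itself")
    total_x = plan.cols * na - (plan.cols - 1) * ox
    total_y = plan.rows * nb - (plan.rows - 1) * oy
    mosaic = np.zeros((total_y, total_x, nz), dtype=np.float32)
    prov = np.full((total_y, total_x), -1, dtype=np.int32)
    weight = (
        np.zeros((total_y, total_x), dtype=np.int32) if policy == "average" else None
    )

    for (r, c), vol in sorted(by_index.items()):
        gy, gx = r * (nb - oy), c * (na - ox)
        if policy == "average" and (ox or oy):
            acc = mosaic[gy : gy + nb, gx : gx + na]
            acc += vol.magnitude
            weight[gy : gy + nb, gx : gx + na] += 1
        else:
            # crop-to-center: keep the central region, splitting each
            # overlap band at its midline between neighbouring tiles
            ky0 = 0 if r == 0 else (oy + 1) // 2
            ky1 = nb if r == plan.rows - 1 else nb - oy // 2
            kx0 = 0 if c == 0 else (ox + 1) // 2
            kx1 = na if c == plan.cols - 1 else na - ox // 2
            mosaic[gy + ky0 : gy + ky1, gx + kx0 : gx + kx1] = vol.magnitude[
                ky0:ky1, kx0:kx1
            ]
        # provenance always follows the crop-to-center ownership rule
        py0 = 0 if r == 0 else (oy + 1) // 2
        py1 = nb if r == plan.rows - 1 else nb - oy // 2
        px0 = 0 if c == 0 else (ox + 1) // 2
        px1 = na if c == plan.cols - 1 else na - ox // 2
        prov[gy + py0 : gy + py1, gx + px0 : gx + px1] = r * plan.cols + c

    if policy == "average" and (ox or oy):
        mosaic /= np.maximum(weight, 1)[:, :, None]

    return MosaicVolume(
        magnitude=mosaic,
        pitch_x_mm=first.pitch_x_mm,
        pitch_y_mm=first.pitch_y_mm,
        pitch_z_um=first.pitch_z_um,
        provenance_map=prov,
        metadata={
            "rows": plan.rows,
            "cols": plan.cols,
            "overlap_mm": plan.overlap_mm,
            "policy": policy,
            "convention": "row 0 = bottom, x rightward, [Y][X][Z]",
        },
    )


def split_volume(
    magnitude: np.ndarray,
    rows: int,
    cols: int,
    *,
    pitch_x_mm: float = 1.0,
    pitch_y_mm: float = 1.0,
    pitch_z_um: float = 1.0,
) -> List[OCTVolume]:
    """Partition a [Y][X][Z] array into a rows×cols tile grid (the exact
    inverse of zero-overlap stitching; used for round-trip checks)."""
    m = np.asarray(magnitude)
    ny, nx, _ = m.shape
    if ny % rows or nx % cols:
        raise ValueError("array extent must divide evenly into the grid")
    nb, na = ny // rows, nx // cols
    return [
        OCTVolume(
            magnitude=np.ascontiguousarray(
                m[r * nb : (r + 1) * nb, c * na : (c + 1) * na]
            ),
            pitch_x_mm=pitch_x_mm,
            pitch_y_mm=pitch_y_mm,
            pitch_z_um=pitch_z_um,
            tile_index=(r, c),
        )
        for r in range(rows)
        for c in range(cols)
    ]
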