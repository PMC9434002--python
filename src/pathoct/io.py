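"""Format readers/writers and artifact checksums.

Raw tiles and calibration arrays live in one HDF5 container; reconstructed
volumes and mosaics are multi-page TIFF (one page per B-scan) with a JSON
sidecar carrying pitches and provenance; projections are PNG/TIFF; plans,
ground truth, manifests and reports are JSON.

Checksums: non-HDF5 artifacts are hashed over their raw bytes.  HDF5
object headers embed creation timestamps that cannot be disabled for
groups, so ``.h5`` files are hashed over their *structural content*
(dataset bytes + sorted attributes) instead — the digest is reproducible
for identical content regardless of when the file was written.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import h5py
import numpy as np
import tifffile

from .calibration import CalibrationSet
from .mosaic import MosaicVolume, ScanPlan
from .phantom_sim import GroundTruth, RawTileVolume
from .recon import OCTVolume

FORMAT_VERSION = 1


def _require_version(attrs) -> None:
    v = int(attrs.get("format_version", -1))
    if v != FORMAT_VERSION:
        raise ValueError(f"unsupported container version {v} (expected {FORMAT_VERSION})")


# ---------------------------------------------------------------------------
# HDF5 raw-tile container
# ---------------------------------------------------------------------------

def write_tiles_h5(path, tiles: List[RawTileVolume]) -> str:
    path = str(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        grp = f.create_group("tiles")
        for t in tiles:
            r, c = t.tile_index
            g = grp.create_group(f"{r}_{c}")
            g.create_dataset("counts", data=t.counts, track_times=False)
            g.create_dataset("reference", data=t.reference, track_times=False)
            g.attrs["stage_x_mm"] = float(t.stage_xy_mm[0])
            g.attrs["stage_y_mm"] = float(t.stage_xy_mm[1])
            g.attrs["seed"] = int(t.seed)
            g.attrs["saturated"] = bool(t.saturated)
    return path


def read_tiles_h5(path) -> List[RawTileVolume]:
    tiles = []
    with h5py.File(str(path), "r") as f:
        _require_version(f.attrs)
        for name in sorted(f["tiles"]):
            g = f["tiles"][name]
            r, c = (int(v) for v in name.split("_"))
            tiles.append(
                RawTileVolume(
                    counts=g["counts"][...],
                    reference=g["reference"][...],
                    stage_xy_mm=(float(g.attrs["stage_x_mm"]), float(g.attrs["stage_y_mm"])),
                    tile_index=(r, c),
                    seed=int(g.attrs["seed"]),
                    saturated=bool(g.attrs["saturated"]),
                )
            )
    return tiles


def write_calibration_h5(path, cal: CalibrationSet) -> str:
    """Calibration arrays under /calibration plus a JSON-encoded header."""
    path = str(path)
    with h5py.File(path, "a") as f:
        if "format_version" not in f.attrs:
            f.attrs["format_version"] = FORMAT_VERSION
        if "calibration" in f:
            del f["calibration"]
        g = f.create_group("calibration")
        g.create_dataset("background", data=cal.background, track_times=False)
        g.create_dataset("k_map", data=cal.k_map, track_times=False)
        g.create_dataset("dispersion_phase", data=cal.dispersion_phase, track_times=False)
        g.attrs["header"] = json.dumps(
            {
                "dispersion_coefficients": list(cal.dispersion_coefficients),
                "k0_rad_per_um": cal.k0_rad_per_um,
                "provenance": cal.provenance,
            },
            sort_keys=True,
        )
    return path


def read_calibration_h5(path) -> CalibrationSet:
    with h5py.File(str(path), "r") as f:
        _require_version(f.attrs)
        g = f["calibration"]
        header = json.loads(g.attrs["header"])
        return CalibrationSet(
            background=g["background"][...],
            k_map=g["k_map"][...],
            dispersion_phase=g["dispersion_phase"][...],
            dispersion_coefficients=tuple(header["dispersion_coefficients"]),
            k0_rad_per_um=header["k0_rad_per_um"],
            provenance=header["provenance"],
        )


# ---------------------------------------------------------------------------
# TIFF volumes with JSON sidecars
# ---------------------------------------------------------------------------

def _sidecar(path: str) -> str:
    return str(Path(path).with_suffix(".json"))


def write_volume_tiff(path, volume: OCTVolume) -> str:
    """One TIFF page per B-scan (float32 linear magnitude)."""
    path = str(path)
    tifffile.imwrite(path, volume.magnitude, photometric="minisblack")
    meta = {
        "kind": "oct_volume",
        "format_version": FORMAT_VERSION,
        "pitch_x_mm": volume.pitch_x_mm,
        "pitch_y_mm": volume.pitch_y_mm,
        "pitch_z_um": volume.pitch_z_um,
        "tile_index": list(volume.tile_index),
        "provenance": volume.provenance,
    }
    Path(_sidecar(path)).write_text(json.dumps(meta, sort_keys=True, indent=1))
    return path


def read_volume_tiff(path) -> OCTVolume:
    path = str(path)
    meta = json.loads(Path(_sidecar(path)).read_text())
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError("unsupported volume sidecar version")
    return OCTVolume(
        magnitude=tifffile.imread(path),
        pitch_x_mm=meta["pitch_x_mm"],
        pitch_y_mm=meta["pitch_y_mm"],
        pitch_z_um=meta["pitch_z_um"],
        tile_index=tuple(meta["tile_index"]),
        provenance=meta.get("provenance", {}),
    )


def write_mosaic_tiff(path, mosaic: MosaicVolume) -> str:
    path = str(path)
    tifffile.imwrite(path, mosaic.magnitude, photometric="minisblack")
    meta = {
        "kind": "mosaic_volume",
        "format_version": FORMAT_VERSION,
        "pitch_x_mm": mosaic.pitch_x_mm,
        "pitch_y_mm": mosaic.pitch_y_mm,
        "pitch_z_um": mosaic.pitch_z_um,
        "provenance_map": mosaic.provenance_map.tolist(),
        "metadata": mosaic.metadata,
    }
    Path(_sidecar(path)).write_text(json.dumps(meta, sort_keys=True))
    return path


def read_mosaic_tiff(path) -> MosaicVolume:
    path = str(path)
    meta = json.loads(Path(_sidecar(path)).read_text())
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError("unsupported mosaic sidecar version")
    return MosaicVolume(
        magnitude=tifffile.imread(path),
        pitch_x_mm=meta["pitch_x_mm"],
        pitch_y_mm=meta["pitch_y_mm"],
        pitch_z_um=meta["pitch_z_um"],
        provenance_map=np.asarray(meta["provenance_map"], dtype=np.int32),
        metadata=meta.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# JSON artifacts
# ---------------------------------------------------------------------------

def write_json(path, obj: dict) -> str:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1, default=_json_default))
    return str(path)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_scan_plan(path, plan: ScanPlan) -> str:
    return write_json(path, json.loads(plan.model_dump_json()))


def read_scan_plan(path) -> ScanPlan:
    return ScanPlan.model_validate_json(Path(path).read_text())


def write_ground_truth(path, truths: List[GroundTruth]) -> str:
    return write_json(
        path,
        {
            "format_version": FORMAT_VERSION,
            "tiles": [
                {
                    "tile_index": list(t.tile_index),
                    "reflectors": t.reflectors,
                    "global_reflectors": t.global_reflectors,
                    "dispersion_coefficients": list(t.dispersion_coefficients),
                    "background": np.round(np.asarray(t.background, float), 3),
                    "seed": t.seed,
                }
                for t in truths
            ],
        },
    )


# ---------------------------------------------------------------------------
# checksums and manifest
# ---------------------------------------------------------------------------

def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def content_digest(path) -> str:
    """Reproducible digest: structural for HDF5, raw bytes otherwise."""
    path = str(path)
    if not path.endswith((".h5", ".hdf5")):
        return sha256_of_file(path)
    h = hashlib.sha256()
    with h5py.File(path, "r") as f:
        def visit(name, obj):
            h.update(name.encode())
            for key in sorted(obj.attrs):
                h.update(key.encode())
                h.update(np.asarray(obj.attrs[key]).tobytes())
            if isinstance(obj, h5py.Dataset):
                h.update(str(obj.dtype).encode())
                h.update(np.ascontiguousarray(obj[...]).tobytes())
        for key in sorted(f.attrs):
            h.update(key.encode())
            h.update(np.asarray(f.attrs[key]).tobytes())
        f.visititems(visit)
    return h.hexdigest()


def build_manifest(
    out_dir, artifacts: Dict[str, str], config: dict, seed: int
) -> dict:
    """Manifest of every artifact with content digests, keyed by relative
    path; reproducible from config + seed alone."""
    out_dir = Path(out_dir)
    return {
        "format_version": FORMAT_VERSION,
        "seed": seed,
        "config": config,
        "artifacts": {
            str(Path(p).relative_to(out_dir)): {
                "stage": stage,
                "sha256": content_digest(p),
            }
            for p, stage in artifacts.items()
        },
    }
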