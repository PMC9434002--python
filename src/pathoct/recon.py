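"""Five-step A-scan reconstruction and volume assembly.

The processing chain converting one raw spectrum into a depth reflectivity
profile executes exactly five steps, in this order:

1. subtract the reference-light background,
2. resample onto the uniform-wavenumber grid (linear-k interpolation),
3. multiply by the apodization window,
4. multiply the analytic signal by ``exp(−i·dispersion_phase)``,
5. discrete Fourier transform (unitary), keeping the positive-depth half.

Step 4 acts on the analytic signal (one-sided spectrum) so that a real
fringe receives a true phase correction.  The depth axis is optical path;
bin pitch is ``max_imaging_depth/(N/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy.signal import hilbert
from scipy.signal.windows import gaussian as gaussian_window

from .calibration import CalibrationSet, resample_to_uniform_k
from .phantom_sim import RawTileVolume
from .system_model import SystemSpec, depth_pitch_um

WINDOWS = ("hann", "gaussian", "rect")


@dataclass
class AScan:
    """Complex reflectivity over N/2 depth bins."""

    values: np.ndarray  # complex [N/2]
    depth_pitch_um: float
    flags: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def depth_axis_um(self) -> np.ndarray:
        return np.arange(self.values.size) * self.depth_pitch_um


@dataclass
class OCTVolume:
    """Reconstructed linear-magnitude volume [B-scans, A-lines, depth]."""

    magnitude: np.ndarray  # float32 [B][A][Z]
    pitch_x_mm: float  # along A-lines (fast axis)
    pitch_y_mm: float  # along B-scans (slow axis)
    pitch_z_um: float
    tile_index: Tuple[int, int] = (0, 0)
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.magnitude.shape


def apodization_window(name: str, n: int) -> np.ndarray:
    """Spectral-shaping window on the uniform-k grid."""
    if name == "hann":
        return np.hanning(n)
    if name == "gaussian":
        return gaussian_window(n, std=n / 6.0, sym=True)
    if name == "rect":
        return np.ones(n)
    raise ValueError(f"unknown window {name!r}; choose from {WINDOWS}")


def reconstruct_ascan(
    raw: np.ndarray,
    cal: CalibrationSet,
    spec: SystemSpec,
    window: str = "hann",
    interp: str = "cubic",
) -> AScan:
    """Run the five processing steps on one raw spectrum."""
    x = np.asarray(raw, dtype=float)
    n = spec.spectrometer.n_pixels
    if x.shape != (n,):
        raise ValueError(f"raw spectrum must have length {n}, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("raw spectrum contains NaN/inf")
    if cal.background.size != n or cal.k_map.size != n:
        raise ValueError("calibration arrays do not match the spectrometer")
    saturated = bool(np.max(x) >= spec.spectrometer.full_well)

    x = x - cal.background  # (1) background subtraction
    x = resample_to_uniform_k(x, cal.k_map, interp)  # (2) linear-k interpolation
    x = x * apodization_window(window, n)  # (3) apodization
    y = hilbert(x)  # analytic signal for a true phase correction
    y = y * np.exp(-1j * cal.dispersion_phase)  # (4) dispersion compensation
    spectrum = np.fft.fft(y) / np.sqrt(n)  # (5) unitary DFT
    return AScan(
        values=spectrum[: n // 2],
        depth_pitch_um=depth_pitch_um(spec.spectrometer),
        flags={"saturated": saturated, "aliased": False},
    )


def reconstruct_volume(
    tile: RawTileVolume,
    cal: CalibrationSet,
    spec: SystemSpec,
    window: str = "hann",
    interp: str = "cubic",
) -> OCTVolume:
    """Apply :func:`reconstruct_ascan` to every column of a raw tile."""
    nb, na, npx = tile.counts.shape
    mag = np.empty((nb, na, npx // 2), dtype=np.float32)
    for b in range(nb):
        for a in range(na):
            mag[b, a] = np.abs(
                reconstruct_ascan(tile.counts[b, a], cal, spec, window, interp).values
            )
    return OCTVolume(
        magnitude=mag,
        pitch_x_mm=spec.tile_fov_mm[0] / na,
        pitch_y_mm=spec.tile_fov_mm[1] / nb,
        pitch_z_um=depth_pitch_um(spec.spectrometer),
        tile_index=tile.tile_index,
        provenance={
            "window": window,
            "interp": interp,
            "seed": tile.seed,
            "saturated": tile.saturated,
        },
    )


def log_compress(magnitude: np.ndarray, dynamic_range_db: float = 40.0) -> np.ndarray:
    """20·log10(m/max), clipped to [−dynamic_range, 0] for display.

    An all-zero input maps to a uniform −dynamic_range image.
    """
    if dynamic_range_db <= 0:
        raise ValueError("dynamic range must be positive")
    m = np.abs(np.asarray(magnitude, dtype=float))
    peak = m.max()
    if peak == 0.0:
        return np.full(m.shape, -dynamic_range_db)
    floor = peak * 10.0 ** (-dynamic_range_db / 20.0 - 2)
    db = 20.0 * np.log10(np.maximum(m, floor) / peak)
    return np.clip(db, -dynamic_range_db, 0.0)
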