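"""Calibration estimators: background, k-linearization map, dispersion phase.

Reconstruction consumes three vectors besides the raw counts:

* ``background`` — the reference-arm spectrum, estimated as the per-pixel
  mean of shutter frames (sample arm blocked);
* ``k_map`` — fractional source-pixel indices that resample a spectrum
  acquired uniformly in wavelength onto samples uniform in wavenumber
  k = 2π/λ (required for a sharp FFT depth peak);
* ``dispersion_phase`` — the residual (order ≥ 2) phase of a mirror fringe
  on the uniform-k grid; multiplying the analytic fringe by
  ``exp(−i·dispersion_phase)`` cancels the sample/reference dispersion
  mismatch.

Dispersion extraction uses the analytic-signal (Hilbert) method: the
one-sided spectrum of a single-reflector fringe is an almost-pure complex
exponential whose unwrapped phase carries the mismatch.  The phase is fit
with a polynomial in (k − k0), weighted by fringe amplitude so the noisy
band edges do not leak in; orders 0 and 1 are discarded (they shift, not
broaden) and the smooth fitted phase is stored.  k0 is fixed at the
uniform-k grid center, which decouples a2/a3 from the linear term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.signal import hilbert

from .system_model import SpectrometerModel, SystemSpec, uniform_k_grid


@dataclass
class CalibrationSet:
    """Everything reconstruction needs besides the raw counts."""

    background: np.ndarray  # [N] counts
    k_map: np.ndarray  # [N] fractional source-pixel indices
    dispersion_phase: np.ndarray  # [N] radians on the uniform-k grid
    dispersion_coefficients: Tuple[float, ...] = ()  # a2, a3, ... rad·(rad/um)^-m
    k0_rad_per_um: Optional[float] = None
    provenance: dict = field(default_factory=dict)


def estimate_background(reference_frames: np.ndarray) -> np.ndarray:
    """Per-pixel mean across a stack of shutter (reference-only) frames."""
    frames = np.asarray(reference_frames, dtype=float)
    if frames.ndim == 1:
        frames = frames[None, :]
    if frames.ndim != 2 or frames.shape[0] < 1:
        raise ValueError("need a non-empty stack of reference spectra")
    return frames.mean(axis=0)


def build_k_mapping(wavelength_map_nm: np.ndarray) -> np.ndarray:
    """Fractional source-pixel index for each uniform-k target sample.

    Sampling the raw spectrum at ``k_map`` yields samples uniform in
    k = 2π/λ between the grid endpoints; the map is strictly increasing
    with ``k_map[0] = 0`` and ``k_map[N−1] = N−1``, and depends only on
    the *shape* of the wavelength map (invariant to uniform scaling).
    """
    lam = np.asarray(wavelength_map_nm, dtype=float)
    if lam.ndim != 1 or lam.size < 2:
        raise ValueError("wavelength map must be a 1-D array of length >= 2")
    d = np.diff(lam)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("wavelength map must be strictly monotone")
    n = lam.size
    k_src = 2.0 * np.pi / lam
    k_target = np.linspace(k_src[0], k_src[-1], n)
    idx = np.arange(n, dtype=float)
    if k_src[0] > k_src[-1]:
        k_map = np.interp(k_target[::-1], k_src[::-1], idx[::-1])[::-1]
    else:
        k_map = np.interp(k_target, k_src, idx)
    k_map[0], k_map[-1] = 0.0, float(n - 1)
    return k_map


def identity_k_map(n: int) -> np.ndarray:
    """The no-resampling map (used to reconstruct *without* k-linearization)."""
    return np.arange(n, dtype=float)


def resample_to_uniform_k(
    spectrum: np.ndarray, k_map: np.ndarray, interp: str = "cubic"
) -> np.ndarray:
    """Sample a raw spectrum at fractional pixel indices ``k_map``."""
    y = np.asarray(spectrum, dtype=float)
    if y.size != k_map.size:
        raise ValueError("spectrum length must match k_map")
    if interp == "linear":
        return np.interp(k_map, np.arange(y.size), y)
    if interp == "cubic":
        return make_interp_spline(np.arange(y.size), y, k=3)(k_map)
    raise ValueError(f"unknown interpolator {interp!r}")


def estimate_dispersion_phase(
    mirror_fringe: np.ndarray,
    background: np.ndarray,
    k_map: np.ndarray,
    spectrometer: SpectrometerModel,
    order: int = 3,
    interp: str = "cubic",
) -> Tuple[np.ndarray, Tuple[float, ...], float]:
    """Extract the dispersion-compensation phase from a mirror fringe.

    Returns ``(phase[N], coefficients, k0)`` where ``phase`` is the fitted
    order-≥2 polynomial sampled on the uniform-k grid (the vector that
    reconstruction multiplies by ``exp(−i·phase)``) and ``coefficients``
    are the equivalent :class:`~pathoct.system_model.DispersionModel`
    coefficients ``(a2, …)`` in rad·(rad/μm)^−m.  Raises ``ValueError`` if
    the fringe does not come from a single dominant reflector (peak less
    than 6 dB above the next-strongest peak).
    """
    if order < 2:
        raise ValueError("polynomial order must be >= 2")
    fringe = np.asarray(mirror_fringe, dtype=float)
    n = fringe.size
    yk = resample_to_uniform_k(fringe - np.asarray(background, float), k_map, interp)
    analytic = hilbert(yk)

    # dominant-peak gate on the one-sided depth spectrum
    mag = np.abs(np.fft.fft(analytic))[: n // 2]
    peak = int(np.argmax(mag))
    guard = max(5, n // 200)
    masked = mag.copy()
    masked[max(0, peak - guard) : peak + guard + 1] = 0.0
    masked[:3] = 0.0  # residual DC
    second = masked.max()
    if second > 0 and 20.0 * np.log10(mag[peak] / second) < 6.0:
        raise ValueError("not a mirror fringe: no dominant single reflector")

    phase = np.unwrap(np.angle(analytic))
    weights = np.abs(analytic)
    weights = weights / weights.max()

    k_grid_um = uniform_k_grid(spectrometer) * 1e3  # rad/um, decreasing
    k0 = float(0.5 * (k_grid_um[0] + k_grid_um[-1]))
    x = k_grid_um - k0
    design = np.vander(x, order + 1, increasing=True)  # columns: x^0 .. x^order
    sw = np.sqrt(weights)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], phase * sw, rcond=None)
    coef_res = coef.copy()
    coef_res[:2] = 0.0  # drop shift terms (order 0 and 1)
    phase_fit = design @ coef_res
    # the analytic phase of cos(2kz + φ_d) on a decreasing-k grid is
    # −(2kz + φ_d): the fitted residual is −φ_d, so the physical model
    # coefficients carry the opposite sign.
    coefficients = tuple(float(-c) for c in coef_res[2:])
    return phase_fit, coefficients, k0


def calibrate(
    reference_frames: np.ndarray,
    spectrometer: SpectrometerModel,
    mirror_fringe: Optional[np.ndarray] = None,
    *,
    wavelength_map_nm: Optional[np.ndarray] = None,
    order: int = 3,
    interp: str = "cubic",
) -> CalibrationSet:
    """Assemble a full :class:`CalibrationSet` from measured frames.

    The pixel→wavelength map is taken as given (spectrometer model or an
    explicit override) — no self-calibration from spectral lines.  Without
    a mirror fringe the dispersion phase is zero.
    """
    background = estimate_background(reference_frames)
    lam = (
        np.asarray(wavelength_map_nm, float)
        if wavelength_map_nm is not None
        else spectrometer.wavelengths()
    )
    k_map = build_k_mapping(lam)
    n = spectrometer.n_pixels
    prov = {"interp": interp, "n_reference_frames": int(np.atleast_2d(reference_frames).shape[0])}
    if mirror_fringe is not None:
        phase, coeffs, k0 = estimate_dispersion_phase(
            mirror_fringe, background, k_map, spectrometer, order=order, interp=interp
        )
        prov["dispersion"] = {"method": "hilbert-polynomial", "order": order}
        return CalibrationSet(background, k_map, phase, coeffs, k0, prov)
    prov["dispersion"] = {"method": "none"}
    return CalibrationSet(background, k_map, np.zeros(n), (), None, prov)


def ideal_calibration(spec: SystemSpec, *, resample: bool = True) -> CalibrationSet:
    """Calibration built from simulator ground truth (no estimation noise).

    Background is the exact reference spectrum ``ρ_R·S(p)``, the k-map is
    derived from the true wavelength map (or identity when ``resample`` is
    False), and the dispersion phase is the exact mismatch phase of
    ``spec.dispersion`` evaluated on the uniform-k grid with the sign that
    step 4 of reconstruction expects.
    """
    spm = spec.spectrometer
    lam = spm.wavelengths()
    background = spec.reference_power_fraction * spec.source.envelope(lam)
    k_map = build_k_mapping(lam) if resample else identity_k_map(spm.n_pixels)
    k_grid_um = uniform_k_grid(spm) * 1e3
    k0 = float(0.5 * (k_grid_um[0] + k_grid_um[-1]))
    phase = -spec.dispersion.phase(k_grid_um, default_k0=k0)
    return CalibrationSet(
        background,
        k_map,
        phase,
        spec.dispersion.coefficients,
        k0,
        {"interp": "cubic", "source": "simulator-truth", "resample": resample},
    )
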