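"""Optical system description and closed-form performance theory.

A spectral-domain OCT (SD-OCT) scanner encodes depth in the spectral
interference fringe of a broadband interferometer read out by a line-scan
spectrometer.  Everything downstream — the fringe simulator, calibration,
the five-step reconstruction chain and the performance metrics — consumes
one :class:`SystemSpec`, the single source of truth for the physics:

* a broadband source (center wavelength ``λ0``, FWHM bandwidth ``Δλ``),
* a spectrometer (``N`` pixels spanning ``λ_min``–``λ_max``, optional
  spectral blur, pixel full well and read noise),
* a dispersion mismatch between sample and reference arms, modelled as a
  polynomial phase of order ≥ 2 in the wavenumber deviation ``k − k0``.

Conventions used throughout the package:

* wavelengths in nm, wavenumber ``k = 2π/λ`` in rad/nm on the pixel grid,
* dispersion polynomial coefficients in rad·(rad/μm)^−m (k-deviation in
  rad/μm so realistic mismatches have coefficients of order 1–100),
* depths are *single-pass optical path* in μm; lateral extents in mm,
* decibel quantities are amplitude dB, ``20·log10``.

The closed forms implemented here are the standard SD-OCT relations:
coherence length ``λ0²/Δλ``; Gaussian-source axial PSF FWHM
``(2 ln 2/π)·λ0²/(Δλ·n)``; Nyquist (maximum) imaging depth
``π/(2 δk)`` for mean wavenumber pitch ``δk``; and the sensitivity
roll-off envelope ``sinc(z·δk)·exp(−2 σ_k² z²)`` combining boxcar pixel
integration with Gaussian spectral blur of standard deviation ``σ_k``.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.optimize import brentq

TWO_PI = 2.0 * np.pi
#: FWHM of a Gaussian = _FWHM_SIGMA_RATIO * sigma
_FWHM_SIGMA_RATIO = 2.0 * np.sqrt(2.0 * np.log(2.0))


class SourceShape(str, Enum):
    gaussian = "gaussian"
    flat_top = "flat_top"
    tabulated = "tabulated"


class SourceSpectrum(BaseModel):
    """Broadband source envelope as seen on the spectrometer.

    ``power_scale`` is the peak envelope level in camera counts before the
    reference-arm power fraction is applied.
    """

    model_config = ConfigDict(frozen=True)

    center_wavelength_nm: float = 850.0
    fwhm_bandwidth_nm: float = 100.0
    shape: SourceShape = SourceShape.gaussian
    power_scale: float = 65535.0
    tabulated_envelope: Optional[Tuple[float, ...]] = None

    @model_validator(mode="after")
    def _check(self) -> "SourceSpectrum":
        if self.center_wavelength_nm <= 0 or self.fwhm_bandwidth_nm <= 0:
            raise ValueError("center wavelength and bandwidth must be positive")
        if self.power_scale <= 0:
            raise ValueError("power_scale must be positive")
        if self.shape is SourceShape.tabulated:
            if self.tabulated_envelope is None:
                raise ValueError("tabulated shape requires tabulated_envelope")
            if any(v < 0 for v in self.tabulated_envelope):
                raise ValueError("tabulated envelope values must be >= 0")
        return self

    def envelope(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Source envelope in counts, sampled at the given wavelengths."""
        lam = np.asarray(wavelengths_nm, dtype=float)
        if self.shape is SourceShape.gaussian:
            arg = (lam - self.center_wavelength_nm) / self.fwhm_bandwidth_nm
            env = np.exp(-4.0 * np.log(2.0) * arg**2)
        elif self.shape is SourceShape.flat_top:
            env = (
                np.abs(lam - self.center_wavelength_nm)
                <= 0.5 * self.fwhm_bandwidth_nm
            ).astype(float)
        else:
            tab = np.asarray(self.tabulated_envelope, dtype=float)
            if tab.size != lam.size:
                raise ValueError(
                    "tabulated envelope length must match the pixel grid"
                )
            peak = tab.max()
            env = tab / peak if peak > 0 else tab
        return self.power_scale * env


class SpectrometerModel(BaseModel):
    """Line-scan spectrometer: pixel grid, blur and camera noise.

    The pixel→wavelength map defaults to linear in λ (grating convention);
    an arbitrary strictly monotone tabulated map is accepted via
    ``wavelength_map_nm``.
    """

    model_config = ConfigDict(frozen=True)

    n_pixels: int = 2048
    lambda_min_nm: float = 750.0
    lambda_max_nm: float = 930.0
    wavelength_map_nm: Optional[Tuple[float, ...]] = None
    # default chosen so the closed-form roll-off envelope reaches −6 dB
    # near 1.1 mm, matching the measured fall-off of the reference system
    spectral_blur_fwhm_nm: float = 0.124
    full_well: int = 65535
    bit_depth: int = 16
    read_noise_counts: float = 6.0
    pixel_integration: bool = True

    @model_validator(mode="after")
    def _check(self) -> "SpectrometerModel":
        if self.n_pixels < 2:
            raise ValueError("spectrometer needs at least 2 pixels")
        if self.spectral_blur_fwhm_nm < 0:
            raise ValueError("spectral blur must be >= 0")
        if self.read_noise_counts < 0:
            raise ValueError("read noise must be >= 0")
        if self.full_well < 1:
            raise ValueError("full well must be >= 1 count")
        if self.wavelength_map_nm is not None:
            lam = np.asarray(self.wavelength_map_nm, dtype=float)
            if lam.size != self.n_pixels:
                raise ValueError("wavelength map length must equal n_pixels")
            d = np.diff(lam)
            if not np.all(d > 0):
                raise ValueError("wavelength map must be strictly increasing")
            object.__setattr__(self, "lambda_min_nm", float(lam[0]))
            object.__setattr__(self, "lambda_max_nm", float(lam[-1]))
        if not self.lambda_max_nm > self.lambda_min_nm > 0:
            raise ValueError("need 0 < lambda_min < lambda_max")
        return self

    def wavelengths(self) -> np.ndarray:
        """λ(p) in nm for pixel index p = 0..N−1 (strictly increasing)."""
        if self.wavelength_map_nm is not None:
            return np.asarray(self.wavelength_map_nm, dtype=float)
        return np.linspace(self.lambda_min_nm, self.lambda_max_nm, self.n_pixels)

    def k_of_pixel(self) -> np.ndarray:
        """k(p) = 2π/λ(p) in rad/nm (strictly decreasing)."""
        return TWO_PI / self.wavelengths()

    def pixel_k_width(self) -> np.ndarray:
        """Local wavenumber width |dk| of each pixel, rad/nm."""
        return np.abs(np.gradient(self.k_of_pixel()))


class DispersionModel(BaseModel):
    """Sample/reference arm dispersion mismatch.

    Phase φ_d(k) = Σ_{m≥2} a_m (k − k0)^m with the k-deviation expressed in
    rad/μm; ``coefficients = (a2, a3, …)``.  Order-0 and order-1 terms are
    structurally absent — they shift the A-scan but do not broaden it.
    """

    model_config = ConfigDict(frozen=True)

    coefficients: Tuple[float, ...] = ()
    k0_rad_per_um: Optional[float] = None

    def phase(self, k_rad_per_um: np.ndarray, default_k0: float) -> np.ndarray:
        """Evaluate the mismatch phase in radians on a wavenumber grid."""
        k = np.asarray(k_rad_per_um, dtype=float)
        k0 = self.k0_rad_per_um if self.k0_rad_per_um is not None else default_k0
        phi = np.zeros_like(k)
        dk = k - k0
        for m, a in enumerate(self.coefficients, start=2):
            if a != 0.0:
                phi += a * dk**m
        return phi


class SystemSpec(BaseModel):
    """Complete optical/acquisition parameter set for one scanner."""

    model_config = ConfigDict(frozen=True)

    source: SourceSpectrum = SourceSpectrum()
    spectrometer: SpectrometerModel = SpectrometerModel()
    dispersion: DispersionModel = DispersionModel()
    na: float = 0.055
    a_line_rate_hz: float = 250e3
    a_lines_per_bscan: int = 1024
    bscans_per_volume: int = 1024
    tile_fov_mm: Tuple[float, float] = (5.0, 5.0)
    tissue_index: float = 1.4
    reference_power_fraction: float = 0.9

    @model_validator(mode="after")
    def _check(self) -> "SystemSpec":
        if not 0.0 < self.na < 1.0:
            raise ValueError("NA must lie in (0, 1)")
        if self.tissue_index < 1.0:
            raise ValueError("tissue refractive index must be >= 1")
        if self.a_lines_per_bscan < 1 or self.bscans_per_volume < 1:
            raise ValueError("scan counts must be >= 1")
        if not 0.0 < self.reference_power_fraction <= 1.0:
            raise ValueError("reference power fraction must lie in (0, 1]")
        if min(self.tile_fov_mm) <= 0:
            raise ValueError("tile field of view must be positive")
        return self


# ---------------------------------------------------------------------------
# closed-form spec calculators
# ---------------------------------------------------------------------------

def coherence_length_um(
    center_wavelength_nm: float, fwhm_bandwidth_nm: float
) -> float:
    """Source coherence length λ0²/Δλ in μm."""
    if center_wavelength_nm <= 0 or fwhm_bandwidth_nm <= 0:
        raise ValueError("wavelength and bandwidth must be positive")
    return center_wavelength_nm**2 / fwhm_bandwidth_nm / 1e3


def axial_resolution_um(
    center_wavelength_nm: float,
    fwhm_bandwidth_nm: float,
    refractive_index: float = 1.0,
) -> float:
    """Gaussian-source axial PSF FWHM (2 ln2/π)·λ0²/(Δλ·n) in μm."""
    if refractive_index < 1.0:
        raise ValueError("refractive index must be >= 1")
    return (
        (2.0 * np.log(2.0) / np.pi)
        * coherence_length_um(center_wavelength_nm, fwhm_bandwidth_nm)
        / refractive_index
    )


def lateral_resolution_um(center_wavelength_nm: float, na: float) -> float:
    """Diffraction-limited lateral FWHM ≈ 0.51·λ0/NA, in μm.

    Exposed for completeness; the closed form assumes a filled Gaussian
    pupil and in-focus imaging.
    """
    if center_wavelength_nm <= 0 or not 0.0 < na < 1.0:
        raise ValueError("need positive wavelength and NA in (0,1)")
    return 0.51 * center_wavelength_nm / na / 1e3


def uniform_k_grid(spectrometer: SpectrometerModel) -> np.ndarray:
    """Uniform-wavenumber target grid in rad/nm.

    Oriented like the pixel grid (k decreasing with index, since λ
    increases), spanning [2π/λ_max, 2π/λ_min] with N samples.
    """
    k_hi = TWO_PI / spectrometer.lambda_min_nm
    k_lo = TWO_PI / spectrometer.lambda_max_nm
    return np.linspace(k_hi, k_lo, spectrometer.n_pixels)


def mean_k_pitch(spectrometer: SpectrometerModel) -> float:
    """Mean wavenumber pitch δk of the uniform-k grid, rad/nm."""
    if spectrometer.n_pixels < 2:
        raise ValueError("need at least 2 pixels")
    span = TWO_PI / spectrometer.lambda_min_nm - TWO_PI / spectrometer.lambda_max_nm
    return span / (spectrometer.n_pixels - 1)


def max_imaging_depth_mm(spectrometer: SpectrometerModel) -> float:
    """Nyquist (alias-free) imaging depth π/(2 δk), in mm of optical path."""
    return np.pi / (2.0 * mean_k_pitch(spectrometer)) / 1e6


def local_alias_free_depth_mm(spectrometer: SpectrometerModel) -> float:
    """Depth alias-free across the *entire* band: π/(2·max_p δk_p), mm.

    A spectrometer linear in λ samples k non-uniformly; the densest pixel
    spacing in k (at the short-wavelength edge) sets the depth beyond
    which part of the fringe is locally undersampled.  Between this depth
    and :func:`max_imaging_depth_mm` reconstruction still localizes a
    reflector but its point spread degrades, since the folded band-edge
    content cannot be recovered by any resampling.
    """
    dk_max = float(np.max(np.abs(np.gradient(spectrometer.k_of_pixel()))))
    return np.pi / (2.0 * dk_max) / 1e6


def depth_pitch_um(spectrometer: SpectrometerModel) -> float:
    """Depth bin pitch of the reconstructed A-scan, μm per bin.

    Equals max_imaging_depth / (N/2): the one-sided DFT of an N-sample
    uniform-k fringe yields N/2 alias-free depth bins.
    """
    return max_imaging_depth_mm(spectrometer) * 1e3 / (spectrometer.n_pixels // 2)


def _blur_sigma_k(spectrometer: SpectrometerModel) -> float:
    """Spectral-blur standard deviation in k (rad/nm) at band center."""
    if spectrometer.spectral_blur_fwhm_nm == 0.0:
        return 0.0
    # band center in k corresponds to the harmonic-mean wavelength
    lam_c = (
        2.0
        * spectrometer.lambda_min_nm
        * spectrometer.lambda_max_nm
        / (spectrometer.lambda_min_nm + spectrometer.lambda_max_nm)
    )
    sigma_lam = spectrometer.spectral_blur_fwhm_nm / _FWHM_SIGMA_RATIO
    return TWO_PI * sigma_lam / lam_c**2


def rolloff_envelope_db(spectrometer: SpectrometerModel, z_mm) -> np.ndarray:
    """Closed-form sensitivity roll-off (amplitude dB, 0 dB at z = 0).

    Combines the sinc envelope of rectangular pixel integration with the
    Gaussian envelope of spectral blur::

        R(z) = sinc(z·δk) · exp(−2 σ_k² z²)

    where sinc(x) = sin(x)/x.  At z = z_max with zero blur the sinc term
    alone gives 20·log10(2/π) ≈ −3.92 dB.
    """
    z = np.atleast_1d(np.asarray(z_mm, dtype=float))
    z_max = max_imaging_depth_mm(spectrometer)
    if np.any(z < 0) or np.any(z > z_max * (1 + 1e-12)):
        raise ValueError(f"depth must lie in [0, {z_max:.4f}] mm")
    z_nm = z * 1e6
    amp = np.ones_like(z_nm)
    if spectrometer.pixel_integration:
        amp *= np.sinc(z_nm * mean_k_pitch(spectrometer) / np.pi)
    sig = _blur_sigma_k(spectrometer)
    if sig > 0.0:
        amp *= np.exp(-2.0 * (sig * z_nm) ** 2)
    db = 20.0 * np.log10(np.maximum(np.abs(amp), 1e-300))
    return db if np.ndim(z_mm) else float(db[0])


def rolloff_6db_depth_theory_mm(
    spectrometer: SpectrometerModel,
) -> Optional[float]:
    """Depth at which the closed-form envelope reaches −6 dB, or None."""
    z_max = max_imaging_depth_mm(spectrometer)

    def f(z):
        return rolloff_envelope_db(spectrometer, z) + 6.0

    if f(z_max) > 0.0:  # never reaches −6 dB inside the alias-free range
        return None
    return float(brentq(f, 0.0, z_max, xtol=1e-9))


def spec_report(spec: SystemSpec) -> str:
    """Human-readable parameter table: configured values alongside the
    computed theory values (coherence length, resolutions, Nyquist depth,
    roll-off).  Tissue-scaled resolution is printed for both the default
    index 1.4 and 1.49."""
    src, spm = spec.source, spec.spectrometer
    lc = coherence_length_um(src.center_wavelength_nm, src.fwhm_bandwidth_nm)
    ax_air = axial_resolution_um(src.center_wavelength_nm, src.fwhm_bandwidth_nm)
    z6 = rolloff_6db_depth_theory_mm(spm)
    rows = [
        ("source center wavelength", f"{src.center_wavelength_nm:g} nm"),
        ("source FWHM bandwidth", f"{src.fwhm_bandwidth_nm:g} nm"),
        ("source shape", src.shape.value),
        ("spectrometer pixels", f"{spm.n_pixels}"),
        ("spectral span", f"{spm.lambda_min_nm:g}-{spm.lambda_max_nm:g} nm"),
        ("spectral blur FWHM", f"{spm.spectral_blur_fwhm_nm:g} nm"),
        ("A-line rate", f"{spec.a_line_rate_hz/1e3:g} kHz"),
        ("A-lines per B-scan", f"{spec.a_lines_per_bscan}"),
        ("tile field of view", f"{spec.tile_fov_mm[0]:g} x {spec.tile_fov_mm[1]:g} mm"),
        ("numerical aperture", f"{spec.na:g}"),
        ("coherence length (theory)", f"{lc:.3f} um"),
        ("axial resolution, air (theory)", f"{ax_air:.3f} um"),
        ("axial resolution, tissue n=1.40", f"{ax_air/1.40:.3f} um"),
        ("axial resolution, tissue n=1.49", f"{ax_air/1.49:.3f} um"),
        (
            "lateral resolution (theory)",
            f"{lateral_resolution_um(src.center_wavelength_nm, spec.na):.3f} um",
        ),
        ("Nyquist imaging depth (theory)", f"{max_imaging_depth_mm(spm):.4f} mm"),
        ("depth pitch", f"{depth_pitch_um(spm):.4f} um/bin"),
        (
            "6-dB roll-off depth (theory)",
            f"{z6:.4f} mm" if z6 is not None else "beyond Nyquist depth",
        ),
    ]
    width = max(len(r[0]) for r in rows)
    return "\n".join(f"{name:<{width}}  {value}" for name, value in rows)
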