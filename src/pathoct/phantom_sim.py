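"""Synthetic spectral-fringe generator with attached ground truth.

Virtual phantoms (discrete reflectors and/or layered scattering slabs)
stand in for fixed tissue blocks, so every downstream stage — calibration,
reconstruction, mosaicking, projections, metrics — can be exercised and
verified without hardware.

The fringe model is the standard SD-OCT interference equation.  For a
column with reflectors ``(z_i, r_i)`` the noiseless spectrum on pixel p is

    C(p) = S(p) · [ ρ_R + Σ_i 2 √ρ_R · r_i · d_i(p) · cos(2 k(p) z_i + φ_d(k(p))) ]

with source envelope ``S``, reference-arm power fraction ``ρ_R``,
dispersion mismatch phase ``φ_d`` and per-pixel damping ``d_i`` collecting
boxcar pixel integration (sinc) and Gaussian spectral blur — both applied
as exact analytic factors on each cosine, which is mathematically identical
to convolving/integrating the continuous spectrum.  Shot noise is Gaussian
with variance equal to the counts (valid at camera count levels), read
noise is additive Gaussian, and counts are clipped to the full well and
rounded to integers.

Depths are single-pass optical path in μm.  All randomness is driven by
``numpy`` seed sequences keyed on ``(seed, stream, bscan, aline)``; layer
scatterers use a *structure* stream independent of the *noise* stream, so
the same phantom realization can be synthesized with and without noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .system_model import (
    TWO_PI,
    _FWHM_SIGMA_RATIO,
    SystemSpec,
    depth_pitch_um,
    max_imaging_depth_mm,
)


class Reflector(BaseModel):
    """Discrete mirror-like reflector.

    ``bscan_range``/``aline_range`` are half-open index ranges of the
    lateral footprint; ``None`` means the full extent.
    """

    model_config = ConfigDict(frozen=True)

    depth_um: float
    reflectivity: float
    bscan_range: Optional[Tuple[int, int]] = None
    aline_range: Optional[Tuple[int, int]] = None

    @model_validator(mode="after")
    def _check(self) -> "Reflector":
        if self.depth_um < 0:
            raise ValueError("reflector depth must be >= 0")
        if not 0.0 <= self.reflectivity <= 1.0:
            raise ValueError("amplitude reflectivity must lie in [0, 1]")
        for rng in (self.bscan_range, self.aline_range):
            if rng is not None and rng[1] <= rng[0]:
                raise ValueError("footprint ranges must be non-empty")
        return self

    def covers(self, bscan: int, aline: int) -> bool:
        if self.bscan_range is not None and not (
            self.bscan_range[0] <= bscan < self.bscan_range[1]
        ):
            return False
        if self.aline_range is not None and not (
            self.aline_range[0] <= aline < self.aline_range[1]
        ):
            return False
        return True


class Layer(BaseModel):
    """Scattering slab: random scatterer phasors within a depth band."""

    model_config = ConfigDict(frozen=True)

    top_um: float
    thickness_um: float
    density_per_voxel: float
    mean_amplitude: float
    amplitude_spread: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "Layer":
        if self.top_um < 0 or self.thickness_um <= 0:
            raise ValueError("layer must have top >= 0 and thickness > 0")
        if self.density_per_voxel < 0 or self.mean_amplitude < 0:
            raise ValueError("density and amplitude must be >= 0")
        if self.amplitude_spread < 0:
            raise ValueError("amplitude spread must be >= 0")
        return self


class Phantom(BaseModel):
    """Virtual specimen: reflectors plus optional layered scattering."""

    model_config = ConfigDict(frozen=True)

    reflectors: Tuple[Reflector, ...] = ()
    layers: Tuple[Layer, ...] = ()
    refractive_index: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "Phantom":
        if self.refractive_index < 1.0:
            raise ValueError("refractive index must be >= 1")
        tops = sorted(self.layers, key=lambda L: L.top_um)
        for lo, hi in zip(tops, tops[1:]):
            if lo.top_um + lo.thickness_um > hi.top_um:
                raise ValueError("layers must be non-overlapping, depth-ordered")
        return self


@dataclass
class RawTileVolume:
    """Raw camera counts for one tile plus acquisition metadata."""

    counts: np.ndarray  # [B][A][N]
    reference: np.ndarray  # [M][N] shutter-open, sample-blocked frames
    stage_xy_mm: Tuple[float, float]
    tile_index: Tuple[int, int]  # (row, col)
    seed: int
    saturated: bool = False
    metadata: dict = field(default_factory=dict)


@dataclass
class GroundTruth:
    """What the simulator actually put into a tile."""

    reflectors: List[dict]  # depth_um, reflectivity, bscan/aline ranges
    dispersion_coefficients: Tuple[float, ...]
    background: np.ndarray  # ρ_R · S(p), the true reference spectrum
    seed: int
    tile_index: Tuple[int, int] = (0, 0)
    global_reflectors: Optional[List[dict]] = None  # stitched coordinates


def _column_rng(seed: int, stream: int, bscan: int, aline: int) -> np.random.Generator:
    # zigzag-encode indices so reference frames (negative B-scan indices)
    # get their own streams without colliding with image columns
    def zz(i: int) -> int:
        return 2 * i if i >= 0 else -2 * i - 1

    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, stream, zz(bscan), zz(aline)])
    )


def _column_scatterers(
    phantom: Phantom, spec: SystemSpec, bscan: int, aline: int, seed: int
) -> List[Tuple[float, float]]:
    """Layer scatterers for one column as (depth_um, amplitude) pairs."""
    if not phantom.layers:
        return []
    rng = _column_rng(seed, 0, bscan, aline)
    dz = depth_pitch_um(spec.spectrometer)
    out: List[Tuple[float, float]] = []
    for layer in phantom.layers:
        mean_count = layer.density_per_voxel * layer.thickness_um / dz
        n = int(rng.poisson(mean_count))
        if n == 0:
            continue
        depths = rng.uniform(layer.top_um, layer.top_um + layer.thickness_um, n)
        amps = rng.normal(layer.mean_amplitude, layer.amplitude_spread, n)
        amps = np.clip(amps, 0.0, 1.0)
        out.extend(zip(depths.tolist(), amps.tolist()))
    return out


def simulate_fringe(
    phantom: Phantom,
    spec: SystemSpec,
    column: Tuple[int, int] = (0, 0),
    seed: int = 0,
    *,
    noiseless: bool = False,
    include_autocorrelation: bool = False,
    allow_aliasing: bool = False,
) -> Tuple[np.ndarray, bool]:
    """Synthesize one raw spectrum (N camera counts) for a phantom column.

    Returns ``(counts, saturated)``.  With ``noiseless=True`` shot/read
    noise and quantization are all skipped and the exact float spectrum is
    returned (layer scatterers, which are structure rather than noise, are
    still drawn from the structure stream).
    """
    bscan, aline = column
    spm = spec.spectrometer
    lam = spm.wavelengths()
    k_nm = TWO_PI / lam
    s_env = spec.source.envelope(lam)
    rho = spec.reference_power_fraction

    z_max_um = max_imaging_depth_mm(spm) * 1e3
    terms: List[Tuple[float, float]] = [
        (r.depth_um, r.reflectivity)
        for r in phantom.reflectors
        if r.covers(bscan, aline)
    ]
    terms += _column_scatterers(phantom, spec, bscan, aline, seed)

    for z_um, _ in terms:
        if z_um > z_max_um:
            if not allow_aliasing:
                raise ValueError(
                    f"reflector at {z_um:.1f} um exceeds the Nyquist depth "
                    f"{z_max_um:.1f} um"
                )
            warnings.warn(
                "reflector beyond Nyquist depth: synthesizing aliased fringe",
                stacklevel=2,
            )

    dk_pixel = spm.pixel_k_width() if spm.pixel_integration else None
    if spm.spectral_blur_fwhm_nm > 0.0:
        sigma_k = TWO_PI * (spm.spectral_blur_fwhm_nm / _FWHM_SIGMA_RATIO) / lam**2
    else:
        sigma_k = None
    k0_um = 1e3 * 0.5 * (TWO_PI / spm.lambda_min_nm + TWO_PI / spm.lambda_max_nm)
    phi_d = spec.dispersion.phase(k_nm * 1e3, default_k0=k0_um)

    def _damp(z_nm: float) -> np.ndarray:
        d = np.ones_like(lam)
        if dk_pixel is not None:
            d = d * np.sinc(z_nm * dk_pixel / np.pi)
        if sigma_k is not None:
            d = d * np.exp(-2.0 * (sigma_k * z_nm) ** 2)
        return d

    ac = np.zeros_like(lam)
    for z_um, r in terms:
        z_nm = z_um * 1e3
        ac += (
            2.0 * np.sqrt(rho) * r * _damp(z_nm) * np.cos(2.0 * k_nm * z_nm + phi_d)
        )
    if include_autocorrelation:
        for i in range(len(terms)):
            for j in range(i + 1, len(terms)):
                dz_nm = (terms[i][0] - terms[j][0]) * 1e3
                ac += (
                    2.0
                    * terms[i][1]
                    * terms[j][1]
                    * _damp(abs(dz_nm))
                    * np.cos(2.0 * k_nm * dz_nm)
                )

    counts = s_env * (rho + ac)

    if noiseless:
        saturated = bool(np.any(counts > spm.full_well))
        if saturated:
            counts = np.clip(counts, 0.0, float(spm.full_well))
        return counts, saturated

    rng = _column_rng(seed, 1, bscan, aline)
    counts = counts + rng.normal(0.0, np.sqrt(np.clip(counts, 0.0, None)))
    if spm.read_noise_counts > 0:
        counts = counts + rng.normal(0.0, spm.read_noise_counts, counts.size)
    saturated = bool(np.any(counts > spm.full_well))
    counts = np.clip(np.round(counts), 0, spm.full_well)
    dtype = np.uint16 if spm.full_well <= np.iinfo(np.uint16).max else np.uint32
    return counts.astype(dtype), saturated


def simulate_tile(
    phantom: Phantom,
    spec: SystemSpec,
    stage_xy_mm: Tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    *,
    tile_index: Tuple[int, int] = (0, 0),
    n_reference_frames: int = 16,
    noiseless: bool = False,
    include_autocorrelation: bool = False,
) -> Tuple[RawTileVolume, GroundTruth]:
    """Raster ``simulate_fringe`` over a B×A tile and attach ground truth.

    Reference-only frames (shutter open, sample arm blocked) are synthesized
    as ``ρ_R·S(p)`` plus noise and appended as a separate block; the noise
    streams are keyed on negative B-scan indices so they never collide with
    image columns.
    """
    nb, na = spec.bscans_per_volume, spec.a_lines_per_bscan
    npx = spec.spectrometer.n_pixels
    empty = Phantom(refractive_index=phantom.refractive_index)
    counts0, _ = simulate_fringe(empty, spec, (0, 0), seed, noiseless=True)
    dtype = float if noiseless else (
        np.uint16
        if spec.spectrometer.full_well <= np.iinfo(np.uint16).max
        else np.uint32
    )
    counts = np.empty((nb, na, npx), dtype=dtype)
    saturated = False
    for b in range(nb):
        for a in range(na):
            col, sat = simulate_fringe(
                phantom,
                spec,
                (b, a),
                seed,
                noiseless=noiseless,
                include_autocorrelation=include_autocorrelation,
            )
            counts[b, a] = col
            saturated = saturated or sat
    reference = np.empty((n_reference_frames, npx), dtype=dtype)
    for m in range(n_reference_frames):
        ref, _ = simulate_fringe(empty, spec, (-1 - m, 0), seed, noiseless=noiseless)
        reference[m] = ref
    tile = RawTileVolume(
        counts=counts,
        reference=reference,
        stage_xy_mm=stage_xy_mm,
        tile_index=tile_index,
        seed=seed,
        saturated=saturated,
        metadata={"noiseless": noiseless},
    )
    truth = GroundTruth(
        reflectors=[
            {
                "depth_um": r.depth_um,
                "reflectivity": r.reflectivity,
                "bscan_range": list(r.bscan_range) if r.bscan_range else [0, nb],
                "aline_range": list(r.aline_range) if r.aline_range else [0, na],
            }
            for r in phantom.reflectors
        ],
        dispersion_coefficients=spec.dispersion.coefficients,
        background=counts0,
        seed=seed,
        tile_index=tile_index,
    )
    return tile, truth


def generate_cassette_dataset(
    phantom: Phantom,
    spec: SystemSpec,
    plan,
    seed: int = 0,
    *,
    noiseless: bool = False,
    n_reference_frames: int = 16,
) -> Tuple[List[RawTileVolume], List[GroundTruth]]:
    """Simulate one raw tile per scan-plan entry (serpentine cassette scan).

    The phantom's reflector footprints are interpreted in *global* stitched
    pixel coordinates (B-scan row index across all tile rows, A-line column
    index across all tile columns, zero-overlap convention); each tile
    receives the intersection of every footprint with its own window,
    shifted to local indices.  Ground truth carries both local and global
    coordinates.
    """
    from .mosaic import ScanPlan  # local import to avoid a cycle

    if not isinstance(plan, ScanPlan):
        raise TypeError("plan must be a ScanPlan")
    nb, na = spec.bscans_per_volume, spec.a_lines_per_bscan
    tot_b, tot_a = plan.rows * nb, plan.cols * na
    for r in phantom.reflectors:
        br = r.bscan_range or (0, tot_b)
        ar = r.aline_range or (0, tot_a)
        if br[0] < 0 or br[1] > tot_b or ar[0] < 0 or ar[1] > tot_a:
            raise ValueError(
                f"reflector footprint {br}x{ar} exceeds the plan extent "
                f"{tot_b}x{tot_a}"
            )

    tiles: List[RawTileVolume] = []
    truths: List[GroundTruth] = []
    for pose in plan.tiles:
        row, col = pose.row, pose.col
        b0, a0 = row * nb, col * na
        local_refs = []
        for r in phantom.reflectors:
            br = r.bscan_range or (0, tot_b)
            ar = r.aline_range or (0, tot_a)
            blo, bhi = max(br[0], b0) - b0, min(br[1], b0 + nb) - b0
            alo, ahi = max(ar[0], a0) - a0, min(ar[1], a0 + na) - a0
            if blo < bhi and alo < ahi:
                local_refs.append(
                    Reflector(
                        depth_um=r.depth_um,
                        reflectivity=r.reflectivity,
                        bscan_range=(blo, bhi),
                        aline_range=(alo, ahi),
                    )
                )
        local = Phantom(
            reflectors=tuple(local_refs),
            layers=phantom.layers,
            refractive_index=phantom.refractive_index,
        )
        tile_seed = int(
            np.random.SeedSequence(
                [int(seed) & 0x7FFFFFFF, 2, row, col]
            ).generate_state(1)[0]
            & 0x7FFFFFFF
        )
        tile, truth = simulate_tile(
            local,
            spec,
            stage_xy_mm=(pose.x_mm, pose.y_mm),
            seed=tile_seed,
            tile_index=(row, col),
            noiseless=noiseless,
            n_reference_frames=n_reference_frames,
        )
        truth.global_reflectors = [
            {
                "depth_um": r.depth_um,
                "reflectivity": r.reflectivity,
                "bscan_range": list(r.bscan_range or (0, tot_b)),
                "aline_range": list(r.aline_range or (0, tot_a)),
            }
            for r in phantom.reflectors
        ]
        tiles.append(tile)
        truths.append(truth)
    return tiles, truths
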