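# Methods

## The measurement being modelled

A spectral-domain OCT interferometer splits broadband light between a
reference mirror and the sample; the recombined light is dispersed onto a
line camera.  A reflector at single-pass optical depth `z` modulates the
detected spectrum with a fringe `cos(2 k z)` in wavenumber `k = 2π/λ`, so
the Fourier transform of the spectrum over `k` is a depth reflectivity
profile (A-scan).  Scanning the beam gives B-scans and volumes; moving the
stage in a serpentine grid and stitching gives a cassette-scale mosaic,
which is reviewed through en-face Z-projections.

`pathoct` models one configured instrument end to end.  All depths are
single-pass optical path in μm (index scaling is left to display); all
decibels are amplitude dB (`20·log10`).

## System model and closed forms

The default `SystemSpec` describes a Gaussian source with center
wavelength λ₀ = 850 nm and FWHM bandwidth Δλ = 100 nm read by a 2048-pixel
spectrometer spanning 750–930 nm, linear in λ (grating convention; any
strictly monotone tabulated map is accepted).  Derived quantities:

* coherence length `λ₀²/Δλ` = 7.225 μm;
* Gaussian axial PSF FWHM `(2 ln 2/π)·λ₀²/(Δλ·n)` = 3.188 μm in air;
  tissue values are reported for n = 1.40 (default) and n = 1.49, since
  published tissue/air resolution pairs for comparable systems imply an
  effective index near 1.49;
* Nyquist imaging depth `π/(2 δk)` = 1.983 mm, where δk is the mean pitch
  of the uniform-k grid over `[2π/λ_max, 2π/λ_min]` with N samples, and
  depth pitch `z_max/(N/2)` = 1.937 μm/bin;
* roll-off envelope `R(z) = sinc(z δk)·exp(−2 σ_k² z²)` — rectangular
  pixel integration times Gaussian spectral blur of standard deviation
  σ_k in wavenumber, normalized to 0 dB at z = 0.  With zero blur the
  sinc term alone gives `20·log10(2/π)` ≈ −3.92 dB at the Nyquist depth.

**Local alias-free depth.**  A λ-linear spectrometer samples k
non-uniformly; the densest k-pitch (short-wavelength edge) sets the depth
`π/(2·max δk_p)` ≈ 1.60 mm ≈ 0.81·z_max beyond which part of the fringe
is locally undersampled.  Between this depth and z_max a reflector is
still localized correctly, but its point spread degrades physically —
folded band-edge content cannot be recovered by any resampling (we
verified that quintic/septic interpolation makes it worse, and that a
uniform-k pixel map keeps the PSF width flat to 0.95·z_max).  PSF-fidelity
validation therefore draws depths within 0.8·z_max; the roll-off
characterization, whose 6-dB point lies near 1.1 mm, is unaffected.

**Spectral blur default (0.124 nm FWHM).**  The spectrometer's optical
blur is rarely published.  The default is derived by inverting the
closed-form envelope so that its −6 dB point falls at 1.1 mm, the fall-off
depth measured on the hardware class this toolkit models; this also makes
the simulated and theoretical curves a meaningful cross-check of each
other.  It corresponds to ≈1.4 camera pixels, a realistic figure for a
compact high-speed spectrometer.

**Dispersion model.**  The arm mismatch is a polynomial phase
`φ_d(k) = Σ_{m≥2} a_m (k−k₀)^m` with the k-deviation in rad/μm, so
physically interesting mismatches have `a₂` of order 1–100 (a₂ = 24
roughly triples the Hann-windowed PSF width).  Order-0/1 terms are
structurally absent: they shift the A-scan without broadening it.  k₀ is
fixed at the uniform-k grid center, which decorrelates the estimated a₂/a₃
from the removed linear component.

## Fringe synthesis

For each column the noiseless spectrum is

    C(p) = S(p)·[ρ_R + Σ_i 2√ρ_R · r_i · d_i(p) · cos(2 k(p) z_i + φ_d(k(p)))]

with source envelope S, reference power fraction ρ_R (default 0.9 —
shot-noise-limited operation with the reference near full well), amplitude
reflectivities r_i, and per-pixel damping d_i.  Because the fringe is a
finite sum of cosines, boxcar pixel integration and Gaussian spectral blur
are applied as *exact* analytic factors per cosine — `sinc(z δk_p)` and
`exp(−2 σ_k(p)² z²)` with per-pixel δk_p and σ_k(p) — which is
mathematically identical to integrating/convolving the continuous
spectrum and avoids a second discretization.  Optional autocorrelation
(sample–sample) terms are off by default.

Noise: shot noise is Gaussian with variance equal to the counts (accurate
at camera count levels; the suite verifies a variance/mean slope of 1
within 10%), read noise is additive Gaussian (default 6 counts RMS),
counts are clipped to the 16-bit full well (with a saturation flag) and
rounded.  Randomness derives from `SeedSequence([seed, stream, b, a])`
with separate *structure* (layer scatterers) and *noise* streams, so a
phantom realization is reproducible with and without noise.  Note the
headroom constraint: with ρ_R = 0.9, mirrors with r ≳ 0.05 clip the
camera; validation phantoms use r ≤ 0.05.

Layered scattering media draw a Poisson number of scatterers per column
(density × thickness/depth-pitch) with clipped-Gaussian amplitudes —
enough to test contrast recovery, but not a speckle-statistics or
tissue-optics model.

## Calibration

* **Background**: per-pixel mean of shutter frames (unbiased; RMS error
  shrinks as `σ/√M`).
* **k-map**: fractional source-pixel indices such that sampling the raw
  spectrum at them is uniform in k; strictly increasing with pinned
  endpoints, and invariant to uniform scaling of the wavelength map.
* **Dispersion phase**: from a single-reflector fringe (enforced by a
  6 dB dominant-peak gate), background-subtracted, resampled, Hilbert
  transformed; the unwrapped analytic phase is fit with a polynomial of
  order 3 (configurable) in `(k−k₀)`, weighted by fringe amplitude so the
  dim band edges do not corrupt the fit.  Orders 0–1 are discarded and
  the smooth fitted phase is stored — this keeps the zero-dispersion
  residual below 0.1 rad and makes the stored vector free of shift terms
  by construction.  Sign convention: on the decreasing-k grid the
  analytic phase of `cos(2kz + φ_d)` is `−(2kz + φ_d)`, so the stored
  vector is `−φ_d` and reconstruction multiplies by
  `exp(−i·dispersion_phase)`; reported coefficients are negated back to
  the physical `a_m`.

## Reconstruction

Exactly five steps, in order: (1) subtract background; (2) resample at
the k-map (cubic spline default, linear optional — recorded in
provenance); (3) multiply by the apodization window (Hann default;
Gaussian and rectangular selectable — Hann bounds side lobes at −31 dB at
the cost of main-lobe width); (4) multiply the analytic signal (Hilbert
transform) by `exp(−i·dispersion_phase)` — acting on the analytic signal
is what makes a phase-only correction of a real fringe well defined;
(5) unitary FFT, keeping the N/2 positive-depth bins.  The unitary
convention makes windowed-spectrum energy equal A-scan energy, which the
suite asserts.  Complex values are retained; magnitude is taken at volume
assembly (float32).  Log compression for display is `20·log10(m/max)`
clipped to a configurable dynamic range.

## Mosaicking

`plan_snake_scan` computes `rows = ⌈height/stride⌉`, `cols =
⌈width/stride⌉` with `stride = tile_fov − overlap` (a 1 ppm tolerance
guards against float ratios like 0.8/0.4 rounding up), and emits a
serpentine visit order from the origin corner (default lower-right, where
the specimen sits in the cassette).  Conventions: row 0 is the bottom row,
x increases rightward, mosaic arrays are `[Y][X][Z]`, tiles share the
depth axis verbatim (no Z registration).  Stitching places tiles by
(row, col) only — the visit order never affects the result.  Zero overlap
abuts tiles exactly (split → stitch is bit-exact); positive overlap is
resolved by crop-to-center (overlap band split at its midline; exact for
consistent tiles) or plain averaging.  A provenance map records the owning
tile of every column.

## Projections and metrics

Z-projections compute the five statistics over a half-open depth-bin
window (default: full depth) on linear magnitude; std is the population
value — the projection is a descriptive statistic of the window, not an
estimator from a sample.  Whether to project linear or log data is a
flag; linear is the default.

PSF FWHM is measured on a band-limited interpolation of the complex
A-scan (zero-padding the analytic-domain signal, 8× by default), with a
parabolic apex refinement and linearly interpolated half-maximum
crossings; widths under two native depth bins are flagged
resolution-limited.  The roll-off procedure reconstructs an identical
mirror at bin-centered depths (avoiding scalloping loss), normalizes at
the shallowest depth, and interpolates the −6 dB crossing; the simulated
6-dB depth matches the closed form to well under 1%.  SNR is
`20·log10(peak/σ)` with σ the standard deviation of the noise-region
magnitude, the region excluding the peak by ≥10 bins.

## Validation strategy, problem sizes, and what it does not show

Everything is validated against simulator ground truth, closed forms, or
independent naive reimplementations (projection statistics), plus frozen
golden outputs pinning the processing order.  Scaled-down rasters (e.g.
8 B-scans × 16 A-lines per tile in the demo cassette) keep the full
workflow — including a double pipeline run for determinism — in the
seconds range; the spectral axis is always the full 2048 pixels, since
that is where the physics lives.

Source-limited PSF checks run with spectral blur and pixel integration
disabled, isolating the source spectrum that the Gaussian closed form
describes; those mechanisms are exercised separately by the roll-off
checks.  Even so, the measured air FWHM (≈3.38 μm) sits ~6% above the
3.19 μm closed form: the simulated source is Gaussian in λ, not in k, and
is truncated at the 750/930 nm band edges — real physics of the modelled
instrument, not an estimator bias (a uniform-k pixel map reproduces the
same value at all depths).

Passing tests show the *processing chain* is correct and self-consistent.
They do not show fidelity to real tissue: the phantom model has no
speckle statistics beyond random phasor sums, no confocal gating or
lateral beam profile, no multiple scattering or absorption, and layer
contrast is whatever the user configures.  Published hardware figures for
this instrument class (e.g. 5.52 μm air resolution from a non-Gaussian
multiplexed-SLD spectrum, 95 dB SNR, 3.00 mm quoted imaging range) depend
on unpublished source spectra, spectrometer optics and power levels and
are deliberately not reproduction targets; the toolkit reports what its
own configured model computes.

## Known limitations

* Wavelength-axis self-calibration (gas cell / etalon) is out of scope;
  the pixel→wavelength map is taken as given.
* Interpolation-based k-linearization contributes its own gentle
  roll-off at depths approaching the local alias-free limit; this is
  inherent to resampling and shared by real processing chains.
* The dispersion estimator requires a single dominant reflector and
  unambiguous phase unwrapping; heavily saturated or multi-reflector
  fringes are rejected rather than handled.
* No GPU/real-time path, no feature-based tile registration, no
  illumination flattening, no tissue-surface segmentation.
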