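"""Performance-metric procedures: PSF width, roll-off, SNR."""

import numpy as np
import pytest

from pathoct.calibration import ideal_calibration
from pathoct.metrics import (
    NoiselessInputWarning,
    ResolutionLimitedWarning,
    characterize,
    measure_psf_fwhm,
    measure_snr,
    sensitivity_falloff,
)
from pathoct.phantom_sim import Phantom, Reflector, simulate_fringe
from pathoct.recon import AScan, apodization_window, reconstruct_ascan
from pathoct.system_model import (
    SystemSpec,
    axial_resolution_um,
    depth_pitch_um,
    local_alias_free_depth_mm,
    rolloff_6db_depth_theory_mm,
)

from conftest import mirror_ascan


def _gaussian_ascan(sigma_bins=4.0, center=100.3, n=512, pitch=2.0):
    z = np.arange(n)
    mag = np.exp(-0.5 * ((z - center) / sigma_bins) ** 2)
    # alternating phase centers the implied fringe in the acquisition
    # window (magnitude unchanged), as a physical reconstruction would
    vals = mag * (-1.0) ** z
    return AScan(values=vals.astype(complex), depth_pitch_um=pitch)


class TestPsfFwhm:
    def test_gaussian_peak_matches_closed_form(self):
        sigma = 4.0
        ascan = _gaussian_ascan(sigma_bins=sigma)
        fwhm = measure_psf_fwhm(ascan)
        assert fwhm == pytest.approx(2.3548 * sigma * 2.0, rel=0.02)

    def test_single_bin_impulse_flagged_resolution_limited(self):
        vals = np.zeros(256, dtype=complex)
        vals[60] = 1.0
        ascan = AScan(values=vals, depth_pitch_um=2.0)
        with pytest.warns(ResolutionLimitedWarning):
            fwhm = measure_psf_fwhm(ascan, check_dominant=False)
        assert fwhm < 1.5 * ascan.depth_pitch_um

    def test_simulated_mirror_matches_gaussian_theory(self, clean_spec):
        ascan = mirror_ascan(clean_spec, 500.0, window="rect")
        theory = axial_resolution_um(850, 100, 1.0)
        assert measure_psf_fwhm(ascan) == pytest.approx(theory, rel=0.10)

    def test_two_comparable_peaks_rejected(self):
        vals = np.zeros(256, dtype=complex)
        vals[60] = 1.0
        vals[180] = 0.9
        with pytest.raises(ValueError, match="dominant"):
            measure_psf_fwhm(AScan(values=vals, depth_pitch_um=2.0))


class TestSensitivityFalloff:
    def test_flat_without_decay_mechanisms(self, uniform_k_spec):
        # no blur, no pixel integration, identity resampling: no decay
        # mechanism remains, so the curve stays flat across the range
        from pathoct.system_model import max_imaging_depth_mm

        z_hi = 0.95 * max_imaging_depth_mm(uniform_k_spec.spectrometer)
        depths = np.linspace(0.1, z_hi, 8)
        _, curve, z6 = sensitivity_falloff(uniform_k_spec, depths_mm=depths)
        assert np.all(np.abs(curve) <= 0.1)
        assert z6 is None

    def test_6db_depth_matches_envelope_theory(self, full_spec):
        _, curve, z6 = sensitivity_falloff(full_spec)
        theory = rolloff_6db_depth_theory_mm(full_spec.spectrometer)
        assert z6 == pytest.approx(theory, rel=0.05)

    def test_curve_monotone_non_increasing(self, full_spec):
        _, curve, _ = sensitivity_falloff(full_spec)
        assert np.all(np.diff(curve) <= 0.05)

    def test_too_few_depths_rejected(self, full_spec):
        with pytest.raises(ValueError, match="5"):
            sensitivity_falloff(full_spec, depths_mm=[0.2, 0.5, 1.0])


class TestSnr:
    @staticmethod
    def _noisy_ascan(peak_amp, noise_sigma, seed=0, n=512):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, noise_sigma, n) + 1j * rng.normal(0, noise_sigma, n)
        vals[200] += peak_amp
        return AScan(values=vals, depth_pitch_um=2.0)

    def test_tenfold_reflectivity_adds_20_db(self):
        a1 = self._noisy_ascan(1000.0, 1.0, seed=5)
        a2 = self._noisy_ascan(10000.0, 1.0, seed=5)
        s1 = measure_snr(a1, (250, 500))
        s2 = measure_snr(a2, (250, 500))
        assert s2 - s1 == pytest.approx(20.0, abs=0.1)

    def test_noiseless_input_flagged_infinite(self):
        vals = np.zeros(512, dtype=complex)
        vals[100] = 1000.0
        ascan = AScan(values=vals, depth_pitch_um=2.0)
        with pytest.warns(NoiselessInputWarning):
            snr = measure_snr(ascan, (300, 500))
        assert np.isinf(snr)

    def test_noise_region_must_exclude_peak(self):
        ascan = self._noisy_ascan(1000.0, 1.0)
        with pytest.raises(ValueError, match="exclude"):
            measure_snr(ascan, (195, 300))

    def test_read_noise_snr_matches_prediction(self, uniform_k_spec):
        # uniform-k pixel map: the resampling step is the identity, so the
        # unitary-DFT noise propagation is exact.  Prediction: peak
        # (1/sqrt(N)) sum A(p) w(p) over Rayleigh noise-magnitude std with
        # per-component sigma from read + shot noise through the window.
        spec = uniform_k_spec.model_copy(
            update={
                "spectrometer": uniform_k_spec.spectrometer.model_copy(
                    update={"read_noise_counts": 20.0}
                )
            }
        )
        n = spec.spectrometer.n_pixels
        dz = depth_pitch_um(spec.spectrometer)
        z_um = 300 * dz  # exactly on a depth bin
        r = 0.02
        lam = spec.spectrometer.wavelengths()
        s_env = spec.source.envelope(lam)
        w = apodization_window("hann", n)
        rho = spec.reference_power_fraction
        peak_pred = np.sum(2 * np.sqrt(rho) * r * s_env * w) / np.sqrt(n)
        var_px = spec.spectrometer.read_noise_counts**2 + rho * s_env
        sigma_mag = np.sqrt((4 - np.pi) / 2) * np.sqrt(2 * np.mean(w**2 * var_px))
        predicted = 20 * np.log10(peak_pred / sigma_mag)

        cal = ideal_calibration(spec)
        ph = Phantom(reflectors=(Reflector(depth_um=z_um, reflectivity=r),))
        hits = 0
        for seed in range(8):
            fringe, _ = simulate_fringe(ph, spec, seed=seed)
            ascan = reconstruct_ascan(fringe, cal, spec, "hann")
            measured = measure_snr(ascan, (400, 1000))
            hits += abs(measured - predicted) <= 1.0
        assert hits >= 7


class TestFullLoopRecovery:
    def test_depth_amplitude_and_dispersion_recovered(self, clean_spec):
        # simulate -> calibrate -> reconstruct -> measure for random
        # (depth, reflectivity, a2) triples
        from pathoct.calibration import CalibrationSet, estimate_dispersion_phase
        from pathoct.system_model import DispersionModel

        from pathoct.metrics import oversampled_magnitude

        rng = np.random.default_rng(21)
        cal0 = ideal_calibration(clean_spec)
        z_lo = 100.0
        z_hi = 0.8 * local_alias_free_depth_mm(clean_spec.spectrometer) * 1e3
        # well-separated reflectivities so rank order is a sharp check
        r_values = rng.permutation(np.linspace(0.01, 0.05, 20))
        true_r, est_peaks = [], []
        for r in r_values:
            z = rng.uniform(z_lo, z_hi)
            r = float(r)
            a2 = rng.uniform(2.0, 10.0)
            spec_d = clean_spec.model_copy(
                update={"dispersion": DispersionModel(coefficients=(float(a2),))}
            )
            ph = Phantom(reflectors=(Reflector(depth_um=z, reflectivity=r),))
            fringe, _ = simulate_fringe(ph, spec_d, noiseless=True)
            phase, coeffs, _ = estimate_dispersion_phase(
                fringe, cal0.background, cal0.k_map, clean_spec.spectrometer
            )
            assert coeffs[0] == pytest.approx(a2, rel=0.05)
            ascan = reconstruct_ascan(
                fringe, CalibrationSet(cal0.background, cal0.k_map, phase), spec_d
            )
            peak = int(np.argmax(ascan.magnitude))
            assert abs(peak * ascan.depth_pitch_um - z) <= ascan.depth_pitch_um / 2
            true_r.append(r)
            # band-limited peak height is scalloping-free
            est_peaks.append(oversampled_magnitude(ascan.values, 8).max())
        # amplitude rank order preserved exactly
        assert list(np.argsort(est_peaks)) == list(np.argsort(true_r))


class TestReport:
    def test_characterization_is_deterministic(self, full_spec):
        r1 = characterize(full_spec, seed=3).to_dict()
        r2 = characterize(full_spec, seed=3).to_dict()
        assert r1 == r2

    def test_report_contents(self, full_spec):
        rep = characterize(full_spec, seed=1)
        assert rep.rolloff_6db_depth_mm is not None
        assert rep.rolloff_6db_depth_mm <= 1.99
        assert np.isfinite(rep.snr_db)
        assert rep.axial_fwhm_tissue_um["1.49"] == pytest.approx(
            rep.axial_fwhm_air_um / 1.49
        )
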