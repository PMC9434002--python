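"""Fringe-simulator contracts: physics, determinism, noise statistics."""

import numpy as np
import pytest

from pathoct.calibration import ideal_calibration
from pathoct.mosaic import plan_snake_scan
from pathoct.phantom_sim import (
    Layer,
    Phantom,
    Reflector,
    generate_cassette_dataset,
    simulate_fringe,
    simulate_tile,
)
from pathoct.recon import reconstruct_ascan, reconstruct_volume
from pathoct.system_model import SystemSpec, depth_pitch_um, max_imaging_depth_mm

from conftest import mirror_ascan


class TestFringePhysics:
    def test_empty_phantom_noiseless_equals_reference_background(self, full_spec):
        fringe, sat = simulate_fringe(Phantom(), full_spec, noiseless=True)
        lam = full_spec.spectrometer.wavelengths()
        expected = full_spec.reference_power_fraction * full_spec.source.envelope(lam)
        np.testing.assert_array_equal(fringe, expected)
        assert not sat

    def test_mirror_recovered_within_half_depth_pixel(self, clean_spec):
        ascan = mirror_ascan(clean_spec, 500.0)
        peak = int(np.argmax(ascan.magnitude))
        assert abs(peak * ascan.depth_pitch_um - 500.0) <= ascan.depth_pitch_um / 2

    def test_reflectivity_linearity_two_to_one(self, clean_spec):
        a1 = mirror_ascan(clean_spec, 400.0, reflectivity=0.04)
        a2 = mirror_ascan(clean_spec, 400.0, reflectivity=0.02)
        ratio = a1.magnitude.max() / a2.magnitude.max()
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_reflector_beyond_nyquist_rejected_unless_allowed(self, clean_spec):
        z_bad = max_imaging_depth_mm(clean_spec.spectrometer) * 1e3 + 100
        ph = Phantom(reflectors=(Reflector(depth_um=z_bad, reflectivity=0.1),))
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_fringe(ph, clean_spec, noiseless=True)
        with pytest.warns(UserWarning, match="aliased"):
            simulate_fringe(ph, clean_spec, noiseless=True, allow_aliasing=True)

    def test_saturation_flag_and_full_well_clip(self, full_spec):
        ph = Phantom(reflectors=(Reflector(depth_um=300.0, reflectivity=1.0),))
        counts, sat = simulate_fringe(ph, full_spec, seed=1)
        assert sat
        assert counts.max() <= full_spec.spectrometer.full_well
        assert counts.min() >= 0

    def test_autocorrelation_terms_off_by_default(self, clean_spec):
        ph = Phantom(
            reflectors=(
                Reflector(depth_um=400.0, reflectivity=0.04),
                Reflector(depth_um=430.0, reflectivity=0.04),
            )
        )
        f_off, _ = simulate_fringe(ph, clean_spec, noiseless=True)
        f_on, _ = simulate_fringe(
            ph, clean_spec, noiseless=True, include_autocorrelation=True
        )
        assert not np.allclose(f_off, f_on)
        # the autocorrelation beat sits at the 30 um depth difference
        cal = ideal_calibration(clean_spec)
        mag = np.abs(reconstruct_ascan(f_on - f_off + cal.background, cal, clean_spec).values)
        beat_bin = int(round(30.0 / depth_pitch_um(clean_spec.spectrometer)))
        assert abs(int(np.argmax(mag[2:])) + 2 - beat_bin) <= 2


class TestNoiseStatistics:
    def test_shot_noise_variance_scales_with_mean(self):
        spec = SystemSpec.model_validate(
            {"spectrometer": {"read_noise_counts": 0.0}}
        )
        reps = np.array(
            [simulate_fringe(Phantom(), spec, seed=s)[0] for s in range(120)],
            dtype=float,
        )
        mean_px, var_px = reps.mean(axis=0), reps.var(axis=0)
        mask = mean_px > 100  # quantization negligible above this level
        slope = np.polyfit(mean_px[mask], var_px[mask], 1)[0]
        assert slope == pytest.approx(1.0, rel=0.10)

    def test_counts_are_integer_quantized(self, full_spec):
        counts, _ = simulate_fringe(Phantom(), full_spec, seed=3)
        assert counts.dtype == np.uint16


class TestTileSimulation:
    def test_same_seed_bit_identical(self, small_spec):
        ph = Phantom(reflectors=(Reflector(depth_um=500.0, reflectivity=0.1),))
        t1, _ = simulate_tile(ph, small_spec, seed=42)
        t2, _ = simulate_tile(ph, small_spec, seed=42)
        np.testing.assert_array_equal(t1.counts, t2.counts)
        np.testing.assert_array_equal(t1.reference, t2.reference)

    def test_footprint_locality_noiseless(self, small_spec):
        ph = Phantom(
            reflectors=(
                Reflector(
                    depth_um=400.0,
                    reflectivity=0.1,
                    bscan_range=(1, 2),
                    aline_range=(2, 6),
                ),
            )
        )
        tile, _ = simulate_tile(ph, small_spec, seed=0, noiseless=True)
        bg, _ = simulate_fringe(Phantom(), small_spec, noiseless=True)
        for b in range(small_spec.bscans_per_volume):
            for a in range(small_spec.a_lines_per_bscan):
                inside = b == 1 and 2 <= a < 6
                assert np.allclose(tile.counts[b, a], bg) != inside

    def test_layered_phantom_brighter_inside_layer(self, small_spec):
        ph = Phantom(
            layers=(
                Layer(
                    top_um=300.0,
                    thickness_um=300.0,
                    density_per_voxel=0.5,
                    mean_amplitude=0.05,
                    amplitude_spread=0.01,
                ),
            )
        )
        cal = ideal_calibration(small_spec)
        dz = depth_pitch_um(small_spec.spectrometer)
        lo, hi = int(300 / dz), int(600 / dz)
        wins = 0
        for seed in range(10):
            fringe, _ = simulate_fringe(ph, small_spec, (0, 0), seed=seed, noiseless=True)
            mag = np.abs(reconstruct_ascan(fringe, cal, small_spec).values)
            inside = mag[lo:hi].mean()
            outside = mag[hi + 20 : hi + 20 + (hi - lo)].mean()
            wins += inside > outside
        assert wins >= 9


class TestCassetteDataset:
    def test_tile_count_and_quadrant_depths(self, small_spec):
        plan = plan_snake_scan(10.0, 10.0, small_spec.tile_fov_mm)
        assert plan.rows * plan.cols == 4
        nb, na = small_spec.bscans_per_volume, small_spec.a_lines_per_bscan
        depths = {(0, 0): 300.0, (0, 1): 600.0, (1, 0): 900.0, (1, 1): 1200.0}
        reflectors = tuple(
            Reflector(
                depth_um=z,
                reflectivity=0.1,
                bscan_range=(r * nb, (r + 1) * nb),
                aline_range=(c * na, (c + 1) * na),
            )
            for (r, c), z in depths.items()
        )
        tiles, truths = generate_cassette_dataset(
            Phantom(reflectors=reflectors), small_spec, plan, seed=0, noiseless=True
        )
        assert len(tiles) == 4
        cal = ideal_calibration(small_spec)
        for tile, truth in zip(tiles, truths):
            vol = reconstruct_volume(tile, cal, small_spec)
            z_true = depths[tile.tile_index]
            peak = np.argmax(vol.magnitude[0, 0])
            assert abs(peak * vol.pitch_z_um - z_true) <= vol.pitch_z_um / 2
            assert truth.reflectors[0]["depth_um"] == z_true
            assert truth.global_reflectors is not None

    def test_single_tile_plan_degenerates(self, small_spec):
        plan = plan_snake_scan(4.0, 4.0, small_spec.tile_fov_mm)
        tiles, _ = generate_cassette_dataset(Phantom(), small_spec, plan, seed=1)
        assert len(tiles) == 1
        assert tiles[0].counts.shape == (
            small_spec.bscans_per_volume,
            small_spec.a_lines_per_bscan,
            small_spec.spectrometer.n_pixels,
        )

    def test_footprint_outside_plan_extent_rejected(self, small_spec):
        plan = plan_snake_scan(10.0, 10.0, small_spec.tile_fov_mm)
        ph = Phantom(
            reflectors=(
                Reflector(depth_um=300.0, reflectivity=0.1, aline_range=(0, 999)),
            )
        )
        with pytest.raises(ValueError, match="extent"):
            generate_cassette_dataset(ph, small_spec, plan, seed=0)


class TestPhantomValidation:
    def test_overlapping_layers_rejected(self):
        with pytest.raises(ValueError):
            Phantom(
                layers=(
                    Layer(top_um=0, thickness_um=200, density_per_voxel=1, mean_amplitude=0.1),
                    Layer(top_um=100, thickness_um=200, density_per_voxel=1, mean_amplitude=0.1),
                )
            )

    def test_reflectivity_bounds(self):
        with pytest.raises(ValueError):
            Reflector(depth_um=100.0, reflectivity=1.5)
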