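"""Generator contracts: map statistics, the mean/variance law, conservation."""

import numpy as np
import pytest

from camcheck import (
    CameraSpec,
    GroundTruth,
    WarmupModel,
    make_camera_maps,
    make_ground_truth,
    sensor_geometry,
    simulate_stack,
    simulate_two_camera_view,
    simulate_warmup_series,
)


class TestCameraMaps:
    def test_degenerate_parameters_give_constant_maps(self, cmos):
        maps = make_camera_maps(cmos, shape=(32, 32), hot_fraction=0.0,
                                stripe_amplitude=0.0, pixel_cv=0.0, seed=1)
        assert np.all(maps.offset == cmos.base_offset_adu)
        assert np.all(maps.gain == cmos.base_gain)
        assert np.all(maps.read_noise == cmos.base_read_noise_e)

    def test_hot_pixel_fraction(self, cmos):
        """A 0.11% hot fraction shows up as exactly that exceedance rate."""
        maps = make_camera_maps(cmos, shape=(512, 512), hot_fraction=0.0011,
                                hot_scale=3.0, seed=7)
        threshold = 1.5 * cmos.base_read_noise_e
        frac = np.mean(maps.read_noise > threshold)
        assert frac == pytest.approx(0.0011, abs=1e-4)

    def test_stripe_period_dominates_column_spectrum(self, cmos):
        maps = make_camera_maps(cmos, shape=(64, 256), stripe_amplitude=0.1,
                                stripe_period=8, hot_fraction=0.0,
                                pixel_cv=0.005, seed=3)
        col_means = maps.read_noise.mean(axis=0)
        spectrum = np.abs(np.fft.rfft(col_means - col_means.mean()))
        peak = np.argmax(spectrum[1:]) + 1
        assert peak == 256 // 8

    @pytest.mark.parametrize("kwargs,name", [
        ({"stripe_amplitude": -0.1}, "stripe_amplitude"),
        ({"pixel_cv": -0.01}, "pixel_cv"),
        ({"hot_fraction": 1.5}, "hot_fraction"),
    ])
    def test_invalid_parameters_rejected_by_name(self, cmos, kwargs, name):
        with pytest.raises(ValueError, match=name):
            make_camera_maps(cmos, shape=(8, 8), **kwargs)

    def test_deterministic_for_fixed_seed(self, cmos):
        a = make_camera_maps(cmos, shape=(32, 32), seed=11)
        b = make_camera_maps(cmos, shape=(32, 32), seed=11)
        assert np.array_equal(a.read_noise, b.read_noise)


class TestGeometry:
    @pytest.mark.parametrize("pitch,mag,binning,width", [
        (5.86, 60.0, 1, 97.7),   # large-pixel sensor at 60x
        (3.45, 60.0, 1, 57.5),   # small-pixel sensor at 60x
        (3.45, 60.0, 2, 115.0),  # 2x2 binning doubles the projected width
        (1.0, 1.0, 1, 1000.0),
    ])
    def test_projected_width(self, pitch, mag, binning, width):
        spec = CameraSpec("test", (100, 100), pitch, 12, {660.0: 0.5}, 100, 2.0, 6.0)
        geo = sensor_geometry(spec, mag, binning=binning)
        assert geo["projected_pixel_width_nm"] == pytest.approx(width, rel=1e-3)

    def test_binning_fov_loss(self):
        spec = CameraSpec("test", (100, 100), 3.45, 12, {660.0: 0.5}, 100, 2.0, 6.0)
        assert sensor_geometry(spec, 60, binning=2)["fov_loss_from_binning"] == 0.75
        assert sensor_geometry(spec, 60, binning=1)["fov_loss_from_binning"] == 0.0

    def test_zero_magnification_rejected(self, cmos):
        with pytest.raises(ValueError):
            sensor_geometry(cmos, 0.0)


class TestSimulateStack:
    def test_noise_free_dark_equals_rounded_offset(self, cmos):
        maps = make_camera_maps(cmos, shape=(16, 16), hot_fraction=0.0,
                                stripe_amplitude=0.0, pixel_cv=0.03, seed=2)
        maps.read_noise[:] = 0.0
        stack = simulate_stack(maps, cmos, "dark", 5, seed=0)
        expected = np.rint(maps.offset).astype(np.uint16)
        assert np.all(stack.frames == expected[np.newaxis])

    def test_flat_mean_variance_law(self, cmos):
        """Per-pixel temporal moments follow the photon-transfer identities."""
        g, sr, phi = 2.1, 6.4, 200.0
        maps = make_camera_maps(cmos, shape=(24, 24), hot_fraction=0.0,
                                stripe_amplitude=0.0, pixel_cv=0.0, seed=2)
        stack = simulate_stack(maps, cmos, "flat", 4000, mean_photons=phi, seed=5)
        data = stack.frames.astype(float)
        mean = data.mean(axis=0)
        var = data.var(axis=0, ddof=1)
        assert mean.mean() == pytest.approx(cmos.base_offset_adu + g * phi, rel=0.005)
        # + 1/12 ADU^2 quantization variance from integer rounding
        expected_var = g ** 2 * (phi + sr ** 2) + 1.0 / 12.0
        assert var.mean() == pytest.approx(expected_var, rel=0.02)

    def test_emitter_photon_conservation(self, cmos):
        maps = make_camera_maps(cmos, shape=(32, 32), hot_fraction=0.0,
                                stripe_amplitude=0.0, pixel_cv=0.0, seed=2)
        maps.read_noise[:] = 0.0
        n_det = 1000.0
        truth = GroundTruth(
            emitters=np.array([[1760.0, 1760.0]]),
            photons_per_frame=np.full((200, 1), n_det),  # eta=1 below
            background=0.0, psf_sigma_nm=130.0, wavelength_nm=660.0,
            field_nm=(3520.0, 3520.0),
        )
        spec_unit_qe = CameraSpec("unit", (32, 32), 5.86, 16, {660.0: 1.0},
                                  100.0, 2.1, 6.4)
        stack = simulate_stack(maps, spec_unit_qe, "emitters", 200, truth=truth,
                               projected_pixel_nm=110.0, seed=9)
        electrons = (stack.frames.astype(float) - maps.offset) / maps.gain
        per_frame = electrons.sum(axis=(1, 2))
        assert per_frame.mean() == pytest.approx(n_det, abs=4 * np.sqrt(n_det / 200))

    def test_out_of_roi_emitter_skipped_with_warning(self, cmos, caplog):
        maps = make_camera_maps(cmos, shape=(16, 16), seed=1)
        truth = GroundTruth(
            emitters=np.array([[1e6, 1e6]]),
            photons_per_frame=np.full((3, 1), 500.0),
            background=0.0, psf_sigma_nm=130.0, wavelength_nm=660.0,
            field_nm=(1760.0, 1760.0),
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="camcheck.synthetic_camera"):
            simulate_stack(maps, cmos, "emitters", 3, truth=truth,
                           projected_pixel_nm=110.0, seed=1)
        assert any("outside ROI" in r.message for r in caplog.records)

    def test_clipping_respects_bit_depth(self):
        spec = CameraSpec("tiny", (8, 8), 5.86, 8, {660.0: 0.5}, 200.0, 2.0, 3.0)
        maps = make_camera_maps(spec, shape=(8, 8), seed=0)
        stack = simulate_stack(maps, spec, "flat", 50, mean_photons=500.0, seed=1)
        assert stack.frames.max() <= 255
        assert stack.n_saturated > 0

    def test_bitwise_determinism(self, cmos):
        maps = make_camera_maps(cmos, shape=(16, 16), seed=4)
        a = simulate_stack(maps, cmos, "flat", 20, mean_photons=100.0, seed=42)
        b = simulate_stack(maps, cmos, "flat", 20, mean_photons=100.0, seed=42)
        assert np.array_equal(a.frames, b.frames)


class TestTwoCameraView:
    def _truth(self):
        rng = np.random.default_rng(0)
        return GroundTruth(
            emitters=rng.uniform(500, 3000, size=(5, 2)),
            photons_per_frame=rng.integers(100, 2000, size=(20, 5)).astype(float),
            background=2.0, psf_sigma_nm=130.0, wavelength_nm=660.0,
            field_nm=(3520.0, 3520.0),
        )

    def test_photon_totals_conserved_exactly(self, cmos, scmos):
        truth = self._truth()
        maps_a = make_camera_maps(cmos, shape=(32, 32), seed=1)
        maps_b = make_camera_maps(scmos, shape=(32, 32), seed=2)
        view = simulate_two_camera_view(
            truth, (maps_a, cmos, 109.7), (maps_b, scmos, 107.5), split=0.5, seed=3,
        )
        assert np.array_equal(view.photons_a + view.photons_b,
                              np.rint(truth.photons_per_frame))

    def test_split_one_starves_camera_b(self, cmos, scmos):
        truth = self._truth()
        maps_a = make_camera_maps(cmos, shape=(32, 32), seed=1)
        maps_b = make_camera_maps(scmos, shape=(32, 32), seed=2)
        view = simulate_two_camera_view(
            truth, (maps_a, cmos, 109.7), (maps_b, scmos, 107.5), split=1.0, seed=3,
        )
        assert np.all(view.photons_b == 0)

    def test_balanced_split_expectation(self, cmos):
        truth = self._truth()
        maps = make_camera_maps(cmos, shape=(32, 32), seed=1)
        view = simulate_two_camera_view(
            truth, (maps, cmos, 109.7), (maps, cmos, 109.7), split=0.5, seed=3,
        )
        total = np.rint(truth.photons_per_frame).sum()
        assert view.photons_a.sum() == pytest.approx(0.5 * total, rel=0.02)


class TestWarmup:
    def test_zero_amplitude_is_constant(self):
        model = WarmupModel(T_inf=53.9, delta_T=0.0, tau_min=10.0, noise_sd=0.0)
        _, temps = simulate_warmup_series(model, 30.0)
        assert np.allclose(temps, 53.9)

    def test_noiseless_series_matches_closed_form(self):
        model = WarmupModel(T_inf=53.9, delta_T=30.0, tau_min=12.0, noise_sd=0.0)
        times, temps = simulate_warmup_series(model, 90.0)
        assert np.allclose(temps, 53.9 - 30.0 * np.exp(-times / 12.0))

    def test_equilibration_within_52_minutes(self):
        """With tau = 12 min the housing is within 0.5 degC of the asymptote
        at the 52-minute mark."""
        model = WarmupModel(T_inf=53.9, delta_T=30.0, tau_min=12.0, noise_sd=0.0)
        assert abs(model.temperature(52.0) - 53.9) < 0.5


class TestGroundTruth:
    def test_bead_mode_always_on(self):
        truth = make_ground_truth("grid", 4, photons=500.0, on_probability=1.0,
                                  n_frames=50, seed=1)
        assert np.all(truth.photons_per_frame > 0)

    def test_blinking_on_event_count(self):
        truth = make_ground_truth("random", 30, photons=1000.0,
                                  on_probability=0.01, n_frames=1000, seed=2)
        n_on = np.count_nonzero(truth.photons_per_frame)
        assert abs(n_on - 300) < 4 * np.sqrt(300)

    def test_filament_two_line_geometry(self):
        gap = 40.0
        truth = make_ground_truth("filament", 200, filament_gap_nm=gap,
                                  filament_angle_rad=0.5, n_frames=1,
                                  field_nm=(8000.0, 8000.0), seed=3)
        d = np.array([np.cos(0.5), np.sin(0.5)])
        n = np.array([-d[1], d[0]])
        center = np.array([4000.0, 4000.0])
        offsets = (truth.emitters - center) @ n
        assert np.allclose(np.abs(offsets), gap / 2.0, atol=1e-6)
        assert set(np.sign(offsets)) == {-1.0, 1.0}

    def test_empty_truth_allowed(self):
        truth = make_ground_truth("random", 0, n_frames=10, seed=1)
        assert truth.n_emitters == 0
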