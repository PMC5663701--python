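"""Precision estimators and FRC against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from camcheck import (
    PrecisionModelParams,
    compare_cameras_precision,
    direct_precision,
    frc_curve_from_images,
    frc_resolution,
    mortensen_precision,
    nena,
    render,
)

from conftest import make_table


class TestDirectPrecision:
    def test_identical_positions_give_zero(self):
        df = make_table([100.0] * 5, [200.0] * 5)
        out = direct_precision(df, np.zeros(5, dtype=int))
        assert out.iloc[0].sigma_nm == 0.0

    def test_anisotropic_combination_rule(self):
        rng = np.random.default_rng(0)
        n = 20000
        df = make_table(100 + 3.0 * rng.standard_normal(n),
                        100 + 4.0 * rng.standard_normal(n))
        out = direct_precision(df, np.zeros(n, dtype=int))
        assert out.iloc[0].sigma_nm == pytest.approx(math.sqrt(12.5), rel=0.02)

    def test_isotropic_jitter_within_chi2_bounds(self):
        rng = np.random.default_rng(1)
        n = 1000
        df = make_table(100 + 5.0 * rng.standard_normal(n),
                        100 + 5.0 * rng.standard_normal(n))
        out = direct_precision(df, np.zeros(n, dtype=int))
        assert out.iloc[0].sigma_nm == pytest.approx(5.0, abs=0.25)

    def test_singleton_groups_excluded(self):
        df = make_table([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        out = direct_precision(df, np.array([0, 1, 1]))
        assert len(out) == 1


class TestMortensen:
    def test_shot_noise_limit(self):
        # sigma_a = 100 nm exactly: psf^2 + a^2/12 = 100^2
        a = 7.0
        psf = math.sqrt(100.0 ** 2 - a ** 2 / 12.0)
        p = PrecisionModelParams(N=1e4, psf_sigma_nm=psf, pixel_nm=a,
                                 background=0.0, estimator="MLE")
        assert mortensen_precision(p) == pytest.approx(1.00, abs=0.005)

    def test_halving_signal_costs_sqrt2(self):
        kw = dict(psf_sigma_nm=130.0, pixel_nm=110.0, background=0.0)
        s1 = mortensen_precision(PrecisionModelParams(N=2000.0, **kw))
        s2 = mortensen_precision(PrecisionModelParams(N=1000.0, **kw))
        assert s2 / s1 == pytest.approx(math.sqrt(2.0), rel=1e-6)

    def test_ls_closed_form(self):
        p = PrecisionModelParams(N=500.0, psf_sigma_nm=100.0, pixel_nm=110.0,
                                 background=10.0, estimator="LS")
        sa2 = 100.0 ** 2 + 110.0 ** 2 / 12.0
        tau = 2 * math.pi * 10.0 * sa2 / (500.0 * 110.0 ** 2)
        expected = math.sqrt(sa2 / 500.0 * (16.0 / 9.0 + 4.0 * tau))
        assert mortensen_precision(p) == pytest.approx(expected, rel=1e-12)

    def test_ls_background_free_limit_is_4_over_3(self):
        p = PrecisionModelParams(N=1000.0, psf_sigma_nm=100.0, pixel_nm=1.0,
                                 background=0.0, estimator="LS")
        assert mortensen_precision(p) == pytest.approx(
            (4.0 / 3.0) * 100.0 / math.sqrt(1000.0), rel=1e-3)

    def test_mle_quadrature_matches_adaptive_integration(self):
        """Fixed-node quadrature of the excess factor vs scipy.integrate.quad."""
        from scipy.integrate import quad

        from camcheck.metrics import _mle_excess_factor

        for tau in (0.01, 0.1, 1.0, 10.0):
            ref, _ = quad(lambda t: math.log(t) / (1.0 + t / tau), 0.0, 1.0)
            assert _mle_excess_factor(tau) == pytest.approx(1.0 / (1.0 + ref), rel=1e-6)

    def test_mle_never_worse_than_ls(self):
        for N in (100.0, 1000.0):
            for b in (0.0, 5.0, 50.0):
                kw = dict(N=N, psf_sigma_nm=130.0, pixel_nm=110.0, background=b)
                mle = mortensen_precision(PrecisionModelParams(estimator="MLE", **kw))
                ls = mortensen_precision(PrecisionModelParams(estimator="LS", **kw))
                assert mle <= ls

    def test_monotonicity(self):
        base = dict(psf_sigma_nm=130.0, pixel_nm=110.0, background=10.0,
                    estimator="MLE")
        s = [mortensen_precision(PrecisionModelParams(N=N, **base))
             for N in (200, 500, 1000, 5000)]
        assert all(a > b for a, b in zip(s, s[1:]))
        s = [mortensen_precision(PrecisionModelParams(N=1000.0, psf_sigma_nm=130.0,
                                                      pixel_nm=110.0, background=b))
             for b in (0.0, 5.0, 20.0, 100.0)]
        assert all(a < b for a, b in zip(s, s[1:]))

    def test_invalid_photon_count_rejected(self):
        with pytest.raises(ValueError):
            PrecisionModelParams(N=0.0, psf_sigma_nm=130.0, pixel_nm=110.0)


class TestCompareCameras:
    def test_identical_specs_unity_ratio(self, cmos):
        out = compare_cameras_precision(cmos, cmos, np.array([500.0, 5000.0]))
        assert np.allclose(out["ratio_b_over_a"], 1.0)

    def test_qe_scaling_in_shot_noise_limit(self, cmos, scmos):
        """eta 0.48 vs 0.69 alone predicts a ~20% precision gap."""
        out = compare_cameras_precision(
            cmos, scmos, np.logspace(2.5, 4.5, 7), use_read_noise=False,
        )
        # camera A (cmos) is worse: sigma_cmos / sigma_scmos = sqrt(0.69/0.48)
        expected = math.sqrt(0.69 / 0.48)
        assert np.allclose(1.0 / out["ratio_b_over_a"], expected, rtol=1e-6)

    def test_preset_gap_grows_at_low_signal(self, cmos, scmos):
        out = compare_cameras_precision(
            cmos, scmos, np.logspace(2.5, 4.5, 9), background=10.0,
        )
        gap = 1.0 / out["ratio_b_over_a"]  # cmos disadvantage factor
        assert np.all(np.diff(gap) < 0)  # shrinks as photons increase
        assert np.all(gap > 1.0)


class TestNena:
    def _jitter_table(self, sigma, n_frames=600, n_emitters=25, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(500, 15000, size=(n_emitters, 2))
        # enforce >=600 nm separation so cross pairs stay out of the search radius
        keep = [i for i in range(n_emitters)
                if all(np.hypot(*(base[i] - base[j])) > 600 for j in range(i))]
        base = base[keep]
        xs, ys, frames = [], [], []
        for f in range(n_frames):
            pos = base + rng.normal(0, sigma, size=base.shape)
            xs.extend(pos[:, 0])
            ys.extend(pos[:, 1])
            frames.extend([f] * len(base))
        return make_table(xs, ys, frame=frames)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            nena(make_table([], []))

    def test_recovers_injected_jitter(self):
        df = self._jitter_table(8.0)
        result = nena(df)
        assert result.sigma_nn_nm == pytest.approx(8.0, abs=0.5)

    def test_doubling_jitter_doubles_sigma(self):
        s1 = nena(self._jitter_table(5.0, seed=1)).sigma_nn_nm
        s2 = nena(self._jitter_table(10.0, seed=2)).sigma_nn_nm
        assert s2 / s1 == pytest.approx(2.0, rel=0.1)


class TestRender:
    def test_single_record_histogram(self):
        df = make_table([27.0], [13.0])
        img = render(df, 5.5, mode="histogram", extent_nm=(55.0, 55.0))
        assert img.sum() == 1.0
        assert img[int(13.0 / 5.5), int(27.0 / 5.5)] == 1.0

    def test_normalized_gaussian_unit_mass(self):
        df = make_table([100.0], [100.0], uncertainty=10.0)
        img = render(df, 5.5, mode="normalized_gaussian", extent_nm=(220.0, 220.0))
        assert img.sum() == pytest.approx(1.0, abs=0.01)
        peak = np.unravel_index(np.argmax(img), img.shape)
        assert peak == (int(100 / 5.5), int(100 / 5.5))

    def test_mass_conservation_away_from_edges(self):
        rng = np.random.default_rng(0)
        n = 200
        df = make_table(rng.uniform(100, 900, n), rng.uniform(100, 900, n),
                        uncertainty=rng.uniform(5, 15, n))
        img = render(df, 5.5, mode="normalized_gaussian", extent_nm=(1000.0, 1000.0))
        assert img.sum() == pytest.approx(n, rel=0.01)

    def test_empty_table_zero_image(self):
        img = render(make_table([], []), 10.0, extent_nm=(100.0, 100.0))
        assert img.shape == (10, 10)
        assert np.all(img == 0)


def brute_force_frc(img1, img2, pixel_nm):
    """Direct double loop over frequency-plane samples, one-bin rings."""
    n = img1.shape[0]
    f1 = np.fft.fftshift(np.fft.fft2(img1))
    f2 = np.fft.fftshift(np.fft.fft2(img2))
    center = n // 2
    n_rings = center
    num = np.zeros(n_rings)
    d1 = np.zeros(n_rings)
    d2 = np.zeros(n_rings)
    for i in range(n):
        for j in range(n):
            r = int(math.floor(math.hypot(i - center, j - center)))
            if r < n_rings:
                num[r] += (f1[i, j] * np.conj(f2[i, j])).real
                d1[r] += abs(f1[i, j]) ** 2
                d2[r] += abs(f2[i, j]) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        frc = num / np.sqrt(d1 * d2)
    return np.nan_to_num(frc), np.arange(n_rings) / (n * pixel_nm)


class TestFRC:
    def _structured_halves(self, n=128, seed=0, sigma=2.0):
        rng = np.random.default_rng(seed)
        truth = np.zeros((n, n))
        t = np.linspace(0, 1, 2000)
        rr = (20 + 80 * t).astype(int)
        cc = (20 + 60 * t + 10 * np.sin(8 * t)).astype(int)
        truth[rr % n, cc % n] = 1.0
        from scipy.ndimage import gaussian_filter

        blurred = gaussian_filter(truth, sigma)
        img1 = rng.poisson(blurred * 50).astype(float)
        img2 = rng.poisson(blurred * 50).astype(float)
        return img1, img2

    def test_identical_halves_fully_correlated(self):
        img, _ = self._structured_halves()
        curve = frc_curve_from_images(img, img, 10.0)
        assert np.allclose(curve.frc[curve.frc != 0], 1.0, atol=1e-9)
        assert not curve.reached
        assert curve.bound_nm == 20.0

    def test_independent_noise_decorrelated(self):
        rng = np.random.default_rng(3)
        img1 = rng.poisson(5.0, (128, 128)).astype(float)
        img2 = rng.poisson(5.0, (128, 128)).astype(float)
        curve = frc_curve_from_images(img1, img2, 10.0)
        assert np.mean(np.abs(curve.frc[5:])) < 0.1

    def test_matches_brute_force_ring_oracle(self):
        img1, img2 = self._structured_halves()
        curve = frc_curve_from_images(img1, img2, 10.0)
        oracle_frc, oracle_q = brute_force_frc(img1, img2, 10.0)
        assert np.allclose(curve.frc, oracle_frc, atol=1e-10)
        assert np.allclose(curve.q, oracle_q)

    def test_resolution_invariant_under_translation(self):
        rng = np.random.default_rng(4)
        n = 3000
        xs = rng.uniform(200, 2000, n)
        ys = xs * 0.6 + rng.normal(0, 15.0, n) + 100
        frames = rng.integers(0, 1000, n)
        df = make_table(xs, ys, frame=frames)
        r1 = frc_resolution(df, split="odd_even_frames", render_pixel_nm=10.0)
        shifted = df.copy()
        shifted["x_nm"] += 400.0
        shifted["y_nm"] += 250.0
        r2 = frc_resolution(shifted, split="odd_even_frames", render_pixel_nm=10.0)
        assert r1.reached and r2.reached
        assert r1.resolution_nm == pytest.approx(r2.resolution_nm, rel=0.05)

    def test_empty_half_rejected(self):
        df = make_table([1.0, 2.0], [1.0, 2.0], frame=[0, 2])
        with pytest.raises(ValueError):
            frc_resolution(df, split="frame_blocks", block_frames=500)
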