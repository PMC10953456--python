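"""Image-quality metrics, transition experiment, edge sharpness, SNR, and
the Friedman + Nemenyi statistics."""

import numpy as np
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter

from spiralcine.metrics import (
    edge_sharpness,
    friedman_nemenyi,
    image_metrics,
    snr_estimate,
    transition_experiment,
)
from spiralcine.ssim import ssim


class TestImageMetrics:
    def test_identity_values(self, rng):
        x = rng.uniform(0.1, 1, (16, 16))
        rep = image_metrics(x, x)
        assert rep.nrmse == 0.0
        assert rep.ssim == pytest.approx(1.0)
        assert rep.lape_ratio == pytest.approx(1.0)
        assert np.isinf(rep.psnr)

    def test_toy_nrmse_hand_computed(self):
        recon = np.array([[1.0, 0.0], [0.0, 0.0]])
        truth = np.array([[1.0, 1.0], [0.0, 0.0]])
        # ||recon - truth|| = 1, ||truth|| = sqrt(2)
        rep_nrmse = np.linalg.norm(recon - truth) / np.linalg.norm(truth)
        assert rep_nrmse == pytest.approx(1.0 / np.sqrt(2.0))
        # image_metrics needs SSIM-sized images; embed the toy block
        r = np.zeros((16, 16))
        t = np.zeros((16, 16))
        r[0, 0], t[0, 0], t[0, 1] = 1.0, 1.0, 1.0
        rep = image_metrics(r, t)
        assert rep.nrmse == pytest.approx(1.0 / np.sqrt(2.0))

    def test_blur_reduces_lape_ratio(self, rng):
        truth = rng.uniform(0, 1, (32, 32))
        blurred = gaussian_filter(truth, 1.5)
        rep = image_metrics(blurred, truth)
        assert rep.lape_ratio < 1.0

    def test_all_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            image_metrics(np.ones((16, 16)), np.zeros((16, 16)))

    def test_range_normalized_nrmse(self, rng):
        t = rng.uniform(0, 1, (16, 16))
        r = t + 0.1
        rep = image_metrics(r, t, nrmse_norm="range")
        assert rep.nrmse == pytest.approx(0.1 / (t.max() - t.min()))
        with pytest.raises(ValueError):
            image_metrics(r, t, nrmse_norm="max")

    def test_per_frame_series_reported(self, rng):
        r = rng.uniform(0, 1, (3, 16, 16))
        t = rng.uniform(0.1, 1, (3, 16, 16))
        rep = image_metrics(r, t)
        for key in ("nrmse", "psnr", "ssim", "lape_ratio"):
            assert len(rep.per_frame[key]) == 3


class TestTransitionExperiment:
    @pytest.fixture(scope="class")
    def setup(self, grid32):
        from spiralcine.presets import resolve_preset
        from spiralcine.synthetic_data import PhantomSpec, make_transition_pair
        from spiralcine.trajectory import build_trajectory

        spec = PhantomSpec(grid=grid32, n_frames=16, n_coils=2, seed=11)
        a, b = make_transition_pair(spec, seed=77)
        traj = build_trajectory(
            resolve_preset("optimized"), grid32, 1, samples_per_interleave=128
        )
        return a, b, traj

    def test_series_length_is_twelve(self, setup):
        a, b, traj = setup
        curve = transition_experiment(None, a, b, traj)
        assert curve.shape == (12,)

    def test_no_splice_gives_flat_series(self, setup):
        a, _, traj = setup
        curve = transition_experiment(None, a, a, traj)
        # identical cines: no transition dip at frame 6
        assert np.std(curve) < 0.05
        assert curve.min() > curve.mean() - 0.05

    def test_pre_transition_frames_match_single_cine(self, setup):
        a, b, traj = setup
        spliced = transition_experiment(None, a, b, traj)
        solo = transition_experiment(None, a, a, traj)
        assert spliced[:5] == pytest.approx(solo[:5])

    def test_short_cine_rejected(self, setup, grid32):
        from spiralcine.synthetic_data import PhantomSpec, make_phantom_cine

        a, b, traj = setup
        short = make_phantom_cine(
            PhantomSpec(grid=grid32, n_frames=9, n_coils=2, seed=1)
        )
        with pytest.raises(ValueError):
            transition_experiment(None, short, b, traj)


class TestEdgeSharpness:
    def test_flat_profile_returns_zero(self):
        assert edge_sharpness(np.full(20, 3.3), pixel_mm=1.7) == 0.0

    def test_linear_ramp_gradient(self):
        # 0 -> 1 over 10 mm: constant slope 0.1 / mm survives smoothing.
        profile = np.linspace(0, 1, 21)  # 20 steps x 0.5 mm = 10 mm
        val = edge_sharpness(profile, pixel_mm=0.5)
        assert val == pytest.approx(0.1, rel=1e-6)

    def test_step_matches_polynomial_fit_oracle(self):
        profile = np.zeros(24)
        profile[12:] = 1.0
        pixel_mm = 1.7
        got = edge_sharpness(profile, pixel_mm=pixel_mm, window=9, polyorder=3)

        # Independent oracle: local cubic least-squares fit in each 9-point
        # window, derivative of the fitted polynomial at the window center.
        n = profile.size
        derivs = []
        for i in range(4, n - 4):
            xs = (np.arange(i - 4, i + 5) - i) * pixel_mm
            coef = np.polyfit(xs, profile[i - 4: i + 5], 3)
            derivs.append(abs(coef[2]))  # d/dx at 0 of cubic fit
        assert got == pytest.approx(max(derivs), abs=1e-6)

    def test_even_window_variant_runs(self):
        profile = np.concatenate([np.zeros(10), np.linspace(0, 1, 6), np.ones(10)])
        val = edge_sharpness(profile, pixel_mm=1.0, window=8)
        assert val > 0

    def test_image_with_endpoints(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        val = edge_sharpness(img, endpoints=((16, 4), (16, 28)), pixel_mm=1.7)
        assert val > 0.1

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            edge_sharpness(np.linspace(0, 1, 8), pixel_mm=1.0)


class TestSnrEstimate:
    def test_stated_arithmetic(self):
        img = np.zeros((20, 20))
        img[:10] = 100.0
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 1.0, (10, 20))
        noise = (noise - noise.mean()) / noise.std(ddof=1)  # exact SD 1
        img[10:] = noise
        sig = np.zeros_like(img, dtype=bool)
        sig[:10] = True
        val = snr_estimate(img, sig, ~sig)
        assert val == pytest.approx(66.0, rel=1e-9)

    def test_scale_invariance(self, rng):
        img = rng.uniform(1, 2, (16, 16))
        sig = np.zeros_like(img, dtype=bool)
        sig[:8] = True
        a = snr_estimate(img, sig, ~sig)
        b = snr_estimate(3.7 * img, sig, ~sig)
        assert a == pytest.approx(b)

    def test_rayleigh_background_recovers_true_snr(self):
        # Rayleigh SD is ~0.655 sigma, so 0.66 x mean/SD estimates S/sigma.
        rng = np.random.default_rng(42)
        sigma, signal = 2.0, 50.0
        img = np.empty((200, 100))
        img[:100] = signal
        img[100:] = rng.rayleigh(sigma, (100, 100))
        sig = np.zeros_like(img, dtype=bool)
        sig[:100] = True
        est = snr_estimate(img, sig, ~sig)
        assert est == pytest.approx(signal / sigma, rel=0.05)

    def test_zero_variance_noise_rejected(self):
        img = np.ones((10, 10))
        sig = np.zeros_like(img, dtype=bool)
        sig[:5] = True
        with pytest.raises(ValueError):
            snr_estimate(img, sig, ~sig)


def permutation_friedman_p(scores, n_perm=10000, seed=0):
    """Permutation oracle: shuffle scores within each subject."""
    rng = np.random.default_rng(seed)
    stat_obs, _ = stats.friedmanchisquare(*scores.T)
    count = 0
    for _ in range(n_perm):
        perm = np.apply_along_axis(rng.permutation, 1, scores)
        s, _ = stats.friedmanchisquare(*perm.T)
        if s >= stat_obs - 1e-12:
            count += 1
    return count / n_perm


class TestFriedmanNemenyi:
    def test_identical_columns_not_significant(self):
        scores = np.tile(np.arange(10)[:, None].astype(float), (1, 3))
        res = friedman_nemenyi(scores)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant.any()

    def test_dominant_method_detected_and_matches_permutation_oracle(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 1, (10, 3))
        scores[:, 2] += 15.0  # method 3 uniformly best by a large margin
        res = friedman_nemenyi(scores)
        assert res.p_value < 0.05
        assert res.significant[2, 0] and res.significant[2, 1]
        p_perm = permutation_friedman_p(scores, n_perm=10000)
        assert p_perm < 0.05

    def test_shift_invariance(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(0, 1, (12, 4))
        a = friedman_nemenyi(scores)
        b = friedman_nemenyi(scores + 123.4)
        assert a.p_value == pytest.approx(b.p_value)
        assert np.allclose(a.p_matrix, b.p_matrix)

    def test_matches_reference_friedman_statistic(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(0, 1, (8, 3))
        res = friedman_nemenyi(scores)
        ref_stat, ref_p = stats.friedmanchisquare(*scores.T)
        assert res.statistic == pytest.approx(ref_stat)
        assert res.p_value == pytest.approx(ref_p)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            friedman_nemenyi(np.ones((2, 3)))


def test_metric_ssim_agrees_with_loss_ssim(rng):
    """One SSIM implementation serves both the metric and the loss paths."""
    from spiralcine.network import ssim_loss

    x = rng.uniform(0, 1, (24, 24))
    y = rng.uniform(0, 1, (24, 24))
    rep = image_metrics(x, y)
    assert rep.ssim == pytest.approx(1.0 - ssim_loss(x, y), abs=1e-12)
    assert rep.ssim == pytest.approx(ssim(x, y), abs=1e-12)
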