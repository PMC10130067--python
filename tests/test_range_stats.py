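import numpy as np
import pytest

from fnpgrange.range_stats import (
    DepthProfile,
    bin_ground_truth,
    bootstrap_rl_ground_truth,
    bootstrap_rl_reconstructed,
    bootstrap_sample_size,
    calibrate_shift,
    delta_rl,
    range_landmark,
    rl_normality_pvalue,
)


def profile(counts, centers):
    centers = np.asarray(centers, dtype=float)
    w = centers[1] - centers[0]
    edges = np.concatenate([centers - w / 2, [centers[-1] + w / 2]])
    return DepthProfile(edges=edges, counts=np.asarray(counts, dtype=float))


class TestBinning:
    def test_two_values_one_bin(self):
        p = bin_ground_truth(np.array([10.2, 10.7]), 1.0, (0.0, 50.0))
        assert p.counts.sum() == 2
        assert p.counts[10] == 2

    def test_conservation_and_overflow(self):
        z = np.array([5.0, 25.0, 120.0, -30.0])
        p = bin_ground_truth(z, 1.0, (0.0, 50.0))
        assert p.counts.sum() == 2
        assert p.overflow == 2

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            bin_ground_truth(np.array([]))


class TestRangeLandmark:
    def test_symmetric_profile(self):
        assert range_landmark(profile([1, 2, 1], [10, 20, 30])) == pytest.approx(20.0)

    def test_single_bin(self):
        assert range_landmark(profile([0, 5, 0], [10, 30, 50])) == pytest.approx(30.0)

    def test_translation_equivariance(self):
        p = profile([3, 1, 4, 1, 5], [10, 11, 12, 13, 14])
        q = profile([3, 1, 4, 1, 5], [12, 13, 14, 15, 16])
        assert range_landmark(q) - range_landmark(p) == pytest.approx(2.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            range_landmark(profile([0, 0], [1, 2]))

    def test_sum_profile_between_components(self):
        fn = profile([5, 3, 1, 0, 0], [10, 20, 30, 40, 50])
        pg = profile([0, 0, 1, 3, 5], [10, 20, 30, 40, 50])
        rl_sum = range_landmark(fn + pg)
        assert range_landmark(fn) < rl_sum < range_landmark(pg)


class TestSampleSize:
    def test_ratio_formula(self):
        assert bootstrap_sample_size(500_000, 1e9, 1e7) == 5000

    def test_full_intensity_returns_total(self):
        assert bootstrap_sample_size(1234, 1e8, 1e8) == 1234

    def test_floor_at_one(self):
        assert bootstrap_sample_size(1, 1e9, 1e6) == 1

    def test_extrapolation_warns(self):
        with pytest.warns(RuntimeWarning):
            bootstrap_sample_size(100, 1e6, 1e7)


class TestGroundTruthBootstrap:
    def test_degenerate_parent(self):
        d = bootstrap_rl_ground_truth(np.full(50, 12.3), 20, 200, 1,
                                      support=(0.0, 50.0))
        assert d.sigma == 0.0
        assert d.mean == pytest.approx(12.5)  # center of the containing bin

    def test_clt_scaling(self, rng):
        parent = rng.exponential(20.0, 5000)
        a = bootstrap_rl_ground_truth(parent, 250, 10_000, 2, support=(0, 200))
        b = bootstrap_rl_ground_truth(parent, 1000, 10_000, 3, support=(0, 200))
        assert a.sigma / b.sigma == pytest.approx(2.0, rel=0.1)

    def test_deterministic(self, rng):
        parent = rng.exponential(20.0, 500)
        a = bootstrap_rl_ground_truth(parent, 100, 500, 7, support=(0, 200))
        b = bootstrap_rl_ground_truth(parent, 100, 500, 7, support=(0, 200))
        assert np.array_equal(a.samples, b.samples)

    def test_mean_converges_to_plugin_rl(self, rng):
        parent = rng.gamma(4.0, 5.0, 2000)
        plug_in = range_landmark(bin_ground_truth(parent, 1.0, (0, 200)))
        d = bootstrap_rl_ground_truth(parent, 400, 20_000, 4, support=(0, 200))
        assert d.mean == pytest.approx(plug_in, abs=4 * d.sigma / np.sqrt(400))

    def test_raw_coordinate_mode(self, rng):
        parent = rng.gamma(4.0, 5.0, 2000)
        d = bootstrap_rl_ground_truth(parent, 400, 2000, 5, support=(0, 200),
                                      use_bin_centers=False)
        assert d.mean == pytest.approx(parent.mean(), abs=5 * d.sigma / 20)


class TestReconstructedBootstrap:
    def test_single_bin_degenerate(self):
        p = profile([0, 7, 0], [10, 20, 30])
        d = bootstrap_rl_reconstructed(p, 2.0, 300, 1)
        assert d.sigma == 0.0 and d.mean == pytest.approx(20.0)

    def test_poisson_cv_scaling(self):
        p = profile([50, 80, 30, 10, 5], [10, 20, 30, 40, 50])
        lo = bootstrap_rl_reconstructed(p, 1.0, 10_000, 2)
        hi = bootstrap_rl_reconstructed(p, 100.0, 10_000, 3)
        assert lo.sigma / hi.sigma == pytest.approx(10.0, rel=0.15)

    def test_resampled_totals_match_scale(self):
        p = profile([50, 80, 30], [10, 20, 30])
        scale = 3.0
        rng = np.random.default_rng(4)
        draws = rng.poisson(scale * p.counts, size=(2000, 3))
        total_mean = draws.sum(axis=1).mean()
        expected = scale * p.counts.sum()
        assert total_mean == pytest.approx(expected,
                                           abs=3 * np.sqrt(expected / 2000))

    def test_all_zero_profile_errors(self):
        with pytest.raises(ValueError):
            bootstrap_rl_reconstructed(profile([0, 0], [1, 2]), 1.0, 10, 1)


class TestDeltaAndCalibration:
    def test_identical_distributions(self, rng):
        parent = rng.exponential(15.0, 1000)
        d = bootstrap_rl_ground_truth(parent, 100, 1000, 1, support=(0, 200))
        dd, sd = delta_rl(d, d)
        assert dd == 0.0
        assert sd == pytest.approx(np.sqrt(2) * d.sigma)

    def test_antisymmetry(self, rng):
        parent = rng.exponential(15.0, 1000)
        a = bootstrap_rl_ground_truth(parent, 100, 500, 1, support=(0, 200))
        b = bootstrap_rl_ground_truth(parent + 3, 100, 500, 2, support=(0, 200))
        assert delta_rl(a, b)[0] == pytest.approx(-delta_rl(b, a)[0])

    def test_perfect_line(self):
        x = np.arange(-5, 6, dtype=float)
        slope, intercept, r2 = calibrate_shift(x, 2.0 * x + 1.0)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_constant_response(self):
        slope, _, _ = calibrate_shift(np.arange(5.0), np.ones(5))
        assert slope == 0.0

    def test_degenerate_abscissa(self):
        with pytest.raises(ValueError):
            calibrate_shift(np.ones(5), np.arange(5.0))


def test_normality_helper_accepts_gaussian_rejects_bimodal(rng):
    gauss = rng.normal(10.0, 1.0, 10_000)
    assert rl_normality_pvalue(gauss) > 0.01
    bimodal = np.concatenate([rng.normal(0, 0.1, 5000), rng.normal(5, 0.1, 5000)])
    assert rl_normality_pvalue(bimodal) < 0.01
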