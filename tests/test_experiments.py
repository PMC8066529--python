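"""Split protocol, sweeps, and posterior fusion."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from tracerfuse import (SplitSpec, center_scale, combination_sweep,
                        evaluate_subset, fuse_posteriors, generate_cohort,
                        multi_sample_performance, noise_sweep, pca_sweep,
                        split, training_size_sweep)
from tracerfuse.synthetic import CohortSpec, RegionSpec
from .conftest import two_gaussian_spec


class TestSplit:
    def test_stratified_disjoint_counts(self, sockeye_table):
        train, test = split(sockeye_table, SplitSpec(20, 10, seed=1))
        assert train.n_samples == 60 and test.n_samples == 30
        assert set(train.region_counts().values()) == {20}
        assert set(test.region_counts().values()) == {10}
        assert not set(train.values.index) & set(test.values.index)

    def test_same_seed_same_split(self, sockeye_table):
        a = split(sockeye_table, SplitSpec(20, 10, seed=9))
        b = split(sockeye_table, SplitSpec(20, 10, seed=9))
        assert list(a[0].values.index) == list(b[0].values.index)

    def test_infeasible_counts_error(self, sockeye_table):
        with pytest.raises(ValueError, match="requested"):
            split(sockeye_table, SplitSpec(25, 10, seed=0))


class TestEvaluateSubset:
    def test_chance_on_identical_regions(self, identical_regions_table):
        s = evaluate_subset(identical_regions_table, [0, 1], "lda",
                            n_splits=100, seed=2)
        assert abs(s.overall_performance - 0.5) <= 3 * max(s.overall_se, 0.01)

    def test_perfect_on_separated_cohort(self):
        spec = two_gaussian_spec(mu_a=0.0, mu_b=12.0, n=40, seed=3)
        t = center_scale(generate_cohort(spec))
        s = evaluate_subset(t, [0], "lda", n_splits=50, seed=3)
        assert s.overall_performance > 0.99

    def test_overall_is_mean_of_diagonal(self, sockeye_table):
        s = evaluate_subset(sockeye_table, [0, 1], "lda", n_splits=20, seed=4)
        assert s.overall_performance == pytest.approx(
            np.mean(np.diag(s.matrix)), abs=1e-12)
        np.testing.assert_allclose(s.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_single_tracer_gaussian_matches_phi(self):
        """Large-n holdout accuracy reaches the Φ(1) Bayes ceiling."""
        spec = two_gaussian_spec(mu_a=0.0, mu_b=2.0, n=700, seed=5)
        t = generate_cohort(spec)
        s = evaluate_subset(t, [0], "lda", n_splits=20, seed=5,
                            split_spec=SplitSpec(500, 200))
        assert abs(s.overall_performance - norm.cdf(1.0)) < 0.03


class TestCombinationSweep:
    @pytest.mark.parametrize("p, expected", [(1, 17), (2, 136), (8, 500)])
    def test_subset_counts(self, sockeye_table, p, expected):
        sw = combination_sweep(sockeye_table, "lda", [p], max_combos=500,
                               n_splits=2, seed=6)
        assert len(sw) == expected
        assert sw["subset"].nunique() == expected  # distinct subsets
        assert math.comb(17, p) >= expected

    def test_performance_in_unit_interval(self, sockeye_table):
        sw = combination_sweep(sockeye_table, "nbc", [1, 2], max_combos=10,
                               n_splits=10, seed=7)
        assert sw["overall"].between(0, 1).all()

    def test_p_too_large_errors(self, sockeye_table):
        with pytest.raises(ValueError, match="exceeds"):
            combination_sweep(sockeye_table, "lda", [18], n_splits=2)


class TestFusePosteriors:
    def test_product_rule_worked_example(self):
        p = np.tile([0.6, 0.2, 0.2], (3, 1))
        fused = fuse_posteriors(p, rule="product")
        expect = 0.6**3 / (0.6**3 + 2 * 0.2**3)
        assert fused[0] == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.931, abs=1e-3)

    def test_majority_vote(self):
        p = np.array([[0.6, 0.4], [0.55, 0.45], [0.1, 0.9]])
        np.testing.assert_array_equal(fuse_posteriors(p, rule="vote"), [1.0, 0.0])

    def test_unknown_rule(self):
        with pytest.raises(ValueError, match="rule"):
            fuse_posteriors(np.array([[1.0]]), rule="mean")


class TestMultiSample:
    def test_k1_reduces_to_evaluate_subset(self, sockeye_table):
        base = evaluate_subset(sockeye_table, [0, 1, 2], "lda", n_splits=30, seed=8)
        ms = multi_sample_performance(sockeye_table, [0, 1, 2], "lda",
                                      k_values=[1], n_splits=30, seed=8)
        assert ms["overall"].iloc[0] == pytest.approx(base.overall_performance,
                                                      abs=1e-12)

    def test_k_monotone_when_above_chance(self, sockeye_table):
        ms = multi_sample_performance(sockeye_table, list(range(6)), "lda",
                                      k_values=[1, 2, 5], n_splits=100, seed=9)
        perf = ms["overall"].to_numpy()
        se = ms["overall_se"].to_numpy()
        for i in range(len(perf) - 1):
            assert perf[i + 1] >= perf[i] - 3 * np.hypot(se[i], se[i + 1])

    def test_k_exceeding_test_samples_errors(self, sockeye_table):
        with pytest.raises(ValueError, match="exceeds"):
            multi_sample_performance(sockeye_table, [0], "lda", k_values=[11],
                                     n_splits=2, seed=0)


class TestNoiseSweep:
    def test_tiny_sigma_matches_noiseless(self, sockeye_table):
        clean = combination_sweep(sockeye_table, "lda", [3], max_combos=5,
                                  n_splits=60, seed=10)
        tiny = noise_sweep(sockeye_table, "lda", [3], sigma_grid=[1e-4],
                           max_combos=5, n_splits=60, seed=10)
        assert abs(clean["overall"].mean() - tiny["overall"].mean()) < 0.05

    def test_huge_sigma_drowns_signal(self, sockeye_table):
        noisy = noise_sweep(sockeye_table, "lda", [3], sigma_grid=[10.0],
                            max_combos=5, n_splits=60, seed=11)
        assert abs(noisy["overall"].mean() - 1 / 3) < 0.05

    def test_many_noisy_tracers_beat_few_clean_ones(self, sockeye_table):
        """Fusion buys noise robustness: p=15 at σ=1 beats p=5 at σ≈0."""
        few_clean = noise_sweep(sockeye_table, "lda", [5], sigma_grid=[1e-4],
                                max_combos=15, n_splits=40, seed=12)
        many_noisy = noise_sweep(sockeye_table, "lda", [15], sigma_grid=[1.0],
                                 max_combos=15, n_splits=40, seed=12)
        assert many_noisy["overall"].mean() > few_clean["overall"].mean()


class TestPcaSweep:
    def test_full_rank_projection_equals_lda_on_raw(self, sockeye_table):
        """LDA is affine-equivariant: a full PCA rotation changes nothing."""
        from tracerfuse import pca_fit, pca_project
        proj = pca_project(sockeye_table, pca_fit(sockeye_table))
        raw = evaluate_subset(sockeye_table, list(range(17)), "lda",
                              n_splits=25, seed=13)
        rot = evaluate_subset(proj, list(range(17)), "lda", n_splits=25, seed=13)
        assert abs(raw.overall_performance - rot.overall_performance) < 1e-6

    def test_first_axis_can_be_useless(self):
        """High-variance axis without class signal: k=1 is chance, k=2 is not."""
        # strong u,v correlation puts PC1 along u+v; the class separation
        # lies along the minor axis u−v and survives z-scoring
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        spec = CohortSpec(
            regions=[RegionSpec(name="A", mean=[-0.35, 0.35], covariance=cov),
                     RegionSpec(name="B", mean=[0.35, -0.35], covariance=cov)],
            n_per_region=60, seed=14)
        t = generate_cohort(spec)
        sw = pca_sweep(t, "lda", k_values=[1, 2], n_splits=60, seed=14,
                       split_spec=SplitSpec(40, 20))
        assert abs(sw["overall"].iloc[0] - 0.5) < 0.08
        assert sw["overall"].iloc[1] > 0.9

    def test_adding_axes_gains_then_saturates(self, sockeye_table):
        """Early axes add a lot; past saturation, extra axes may cost a little.

        With 20 training samples per region, LDA's pooled covariance gets
        noisy in 17 dimensions, so the full-rank point can dip slightly below
        the saturated level — the gain curve is monotone up to saturation,
        not beyond.
        """
        sw = pca_sweep(sockeye_table, "lda", k_values=[1, 4, 17],
                       n_splits=40, seed=15)
        perf = sw["overall"].to_numpy()
        se = sw["overall_se"].to_numpy()
        assert perf[1] > perf[0] + 3 * np.hypot(se[0], se[1])
        assert perf[2] > perf[1] - 0.06


class TestTrainingSizeSweep:
    def test_more_training_data_helps(self, sockeye_table):
        sw = training_size_sweep(sockeye_table, list(range(8)), "lda",
                                 n_train_grid=[2, 20], n_splits=80, seed=16)
        lo, hi = sw["overall"].to_numpy()
        se = np.hypot(*sw["overall_se"].to_numpy())
        assert hi > lo + 3 * se

    def test_infeasible_grid_errors(self, sockeye_table):
        with pytest.raises(ValueError, match="requested"):
            training_size_sweep(sockeye_table, [0], "lda", n_train_grid=[21],
                                n_splits=2, seed=0)
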