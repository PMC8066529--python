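"""The three classifiers behind the shared posterior contract."""

import numpy as np
import pytest
from scipy.special import logsumexp

from tracerfuse import (center_scale, evaluate_subset, fit, fit_lda, fit_mlp,
                        fit_nbc, generate_cohort)
from tracerfuse.classifiers import augment_training, nrd0_bandwidth
from .conftest import make_table, two_gaussian_spec

METHOD_KW = {
    "lda": {},
    "nbc": {},
    "mlp": {"augmentation": (20, 0.01), "epochs": 80},
}


def separated_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    x = np.r_[rng.normal(-5, 1, n), rng.normal(5, 1, n)][:, None]
    return make_table(x, "A" * n + "B" * n)


@pytest.mark.parametrize("method", ["lda", "nbc", "mlp"])
class TestSharedContract:
    def test_separated_classes_confident(self, method):
        t = separated_table()
        model = fit(t, [0], method, **METHOD_KW[method])
        p = model.predict_proba(np.array([[4.9]]))
        assert p.shape == (1, 2)
        assert p[0, model.class_labels.index("B")] > 0.99

    def test_rows_are_probabilities(self, method):
        t = separated_table(seed=1)
        model = fit(t, [0], method, **METHOD_KW[method])
        p = model.predict_proba(np.linspace(-8, 8, 50)[:, None])
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((p >= 0) & (p <= 1))

    def test_chance_level_on_identical_regions(self, method, identical_regions_table):
        summary = evaluate_subset(identical_regions_table, [0, 1], method,
                                  n_splits=60, seed=3,
                                  fit_kwargs=METHOD_KW[method] or None)
        se = max(summary.overall_se, 0.01)
        assert abs(summary.overall_performance - 0.5) <= 3 * se

    def test_missing_subset_errors(self, method):
        t = separated_table(seed=2)
        model = fit(t, [0], method, **METHOD_KW[method])
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((3, 4)))


class TestLda:
    def test_identical_distributions_near_uniform_posterior(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, size=(200, 1))
        t = make_table(x, "A" * 100 + "B" * 100)
        p = fit_lda(t, [0]).predict_proba(np.array([[0.0]]))
        np.testing.assert_allclose(p[0], [0.5, 0.5], atol=0.05)

    def test_decision_boundary_at_midpoint(self):
        # equal priors, shared variance: boundary is the mean midpoint
        rng = np.random.default_rng(5)
        x = np.r_[rng.normal(-1, 1, 500), rng.normal(3, 1, 500)][:, None]
        t = make_table(x, "A" * 500 + "B" * 500)
        model = fit_lda(t, [0])
        mid = x[:500].mean() / 2 + x[500:].mean() / 2
        below, above = model.predict(np.array([[mid - 0.2], [mid + 0.2]]))
        assert below == "A" and above == "B"
        p_mid = model.predict_proba(np.array([[mid]]))
        np.testing.assert_allclose(p_mid[0], [0.5, 0.5], atol=0.05)


class TestNbc:
    def test_single_tracer_matches_brute_force_kde(self):
        """One-tracer NBC equals an independently coded univariate KDE Bayes rule."""
        rng = np.random.default_rng(6)
        xa = rng.normal(0, 1, 25)
        xb = rng.normal(1.5, 1.3, 25)
        t = make_table(np.r_[xa, xb][:, None], "A" * 25 + "B" * 25)
        model = fit_nbc(t, [0])
        grid = np.linspace(-4, 6, 101)[:, None]
        got = model.predict_proba(grid)

        def kde_logpdf(q, data):
            h = nrd0_bandwidth(data)
            z = (q[:, None] - data[None, :]) / h
            return logsumexp(-0.5 * z**2, axis=1) - np.log(
                len(data) * h * np.sqrt(2 * np.pi))

        la, lb = kde_logpdf(grid[:, 0], xa), kde_logpdf(grid[:, 0], xb)
        expect = np.exp(la) / (np.exp(la) + np.exp(lb))
        np.testing.assert_allclose(got[:, 0], expect, atol=1e-9)

    def test_density_floor_gives_uniform_posterior(self):
        t = make_table(np.r_[np.random.default_rng(7).normal(0, 0.01, 10),
                             np.random.default_rng(8).normal(1, 0.01, 10)][:, None],
                       "A" * 10 + "B" * 10)
        model = fit_nbc(t, [0])
        p = model.predict_proba(np.array([[1e6]]))  # far outside both KDEs
        np.testing.assert_allclose(p[0], [0.5, 0.5], atol=1e-9)

    def test_constant_tracer_falls_back_to_min_bandwidth(self):
        x = np.c_[np.r_[np.zeros(10), np.ones(10)], np.linspace(0, 1, 20)]
        t = make_table(x, "A" * 10 + "B" * 10)
        model = fit_nbc(t, [0, 1])  # column 0 constant within each class
        p = model.predict_proba(np.array([[0.0, 0.2], [1.0, 0.8]]))
        assert p[0, 0] > 0.9 and p[1, 1] > 0.9

    def test_large_sample_accuracy_approaches_bayes(self):
        """Fitted KDE naive Bayes converges to the Bayes ceiling of the generator."""
        from tracerfuse import bayes_accuracy
        spec = two_gaussian_spec(mu_a=0.0, mu_b=1.5, d=2, n=2000, seed=9)
        table = generate_cohort(spec)
        model = fit_nbc(table, [0, 1])
        test = generate_cohort(spec, seed=10)
        acc = (model.predict(test) == test.region.to_numpy()).mean()
        ceiling = bayes_accuracy(spec, n_mc=100000, seed=11).overall
        assert abs(acc - ceiling) < 0.03


class TestMlp:
    def test_linearly_separable_training_accuracy(self):
        rng = np.random.default_rng(12)
        x = np.r_[rng.normal([-2, -2], 0.5, size=(30, 2)),
                  rng.normal([2, 2], 0.5, size=(30, 2))]
        t = make_table(x, "A" * 30 + "B" * 30)
        model = fit_mlp(t, [0, 1], augmentation=(5, 0.01), epochs=150, seed=0)
        assert (model.predict(t) == t.region.to_numpy()).mean() == 1.0

    def test_degenerate_augmentation_is_identity(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(10, 3))
        out = augment_training(x, repeats=1, sigma=0.0, rng=rng)
        np.testing.assert_array_equal(out, x)

    def test_augmentation_repeats_and_perturbs(self):
        rng = np.random.default_rng(14)
        x = np.zeros((4, 2))
        out = augment_training(x, repeats=10, sigma=0.5, rng=rng)
        assert out.shape == (40, 2)
        assert 0.3 < out.std() < 0.7

    def test_seed_reproducibility(self):
        t = separated_table(seed=15)
        m1 = fit_mlp(t, [0], augmentation=(10, 0.01), epochs=50, seed=3)
        m2 = fit_mlp(t, [0], augmentation=(10, 0.01), epochs=50, seed=3)
        q = np.linspace(-6, 6, 20)[:, None]
        np.testing.assert_array_equal(m1.predict_proba(q), m2.predict_proba(q))

    def test_tracks_lda_on_study_shaped_cohort(self, sockeye_table):
        """Cross-method consistency: the small net lands near LDA's accuracy."""
        subset = list(range(17))
        lda = evaluate_subset(sockeye_table, subset, "lda", n_splits=50, seed=5)
        mlp = evaluate_subset(sockeye_table, subset, "mlp", n_splits=50, seed=5,
                              fit_kwargs={"augmentation": (20, 0.01), "epochs": 60})
        assert abs(mlp.overall_performance - lda.overall_performance) < 0.05

    def test_agrees_with_sklearn_reference_net(self):
        """Independent oracle: sklearn's MLP reaches the same toy accuracy."""
        from sklearn.neural_network import MLPClassifier
        rng = np.random.default_rng(16)
        x = np.r_[rng.normal([-1, 0], 1, size=(100, 2)),
                  rng.normal([1.5, 0.5], 1, size=(100, 2))]
        y = np.array(["A"] * 100 + ["B"] * 100)
        t = make_table(x, y)
        ours = fit_mlp(t, [0, 1], augmentation=(5, 0.01), epochs=200, seed=1)
        ref = MLPClassifier(hidden_layer_sizes=(32,), activation="tanh",
                            max_iter=500, random_state=1).fit(x, y)
        xt = rng.normal([0.25, 0.25], 1.2, size=(400, 2))
        ours_acc = (ours.predict(xt) == "B").mean()
        ref_acc = (ref.predict(xt) == "B").mean()
        assert abs(ours_acc - ref_acc) < 0.08


class TestLabelPermutation:
    @pytest.mark.parametrize("method", ["lda", "nbc"])
    def test_relabelling_permutes_predictions(self, method):
        rng = np.random.default_rng(17)
        x = np.r_[rng.normal(-2, 1, 30), rng.normal(0, 1, 30),
                  rng.normal(2, 1, 30)][:, None]
        labels = "A" * 30 + "B" * 30 + "C" * 30
        t1 = make_table(x, labels)
        swap = {"A": "C", "B": "B", "C": "A"}
        t2 = make_table(x, [swap[c] for c in labels])
        q = np.linspace(-4, 4, 30)[:, None]
        p1 = fit(t1, [0], method).predict(q)
        p2 = fit(t2, [0], method).predict(q)
        assert [swap[c] for c in p1] == list(p2)


def test_unknown_method_lists_valid_ones():
    t = separated_table()
    with pytest.raises(ValueError, match="lda"):
        fit(t, [0], method="svm")
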