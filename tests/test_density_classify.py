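"""Silverman-bandwidth KDE, the Bayes decision rule, LOOCV and subset search."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from phsent import (
    bayes_classify,
    kde_fit,
    loocv_evaluate,
    search_combinations,
    silverman_bandwidth,
)
from phsent.density_classify import EvaluationResult, roc_curve, results_table
from phsent.exceptions import DegenerateBandwidthError


def _matrix(patient, healthy, columns=("m1",)):
    """Assemble an entropy-matrix-like frame from per-group value arrays."""
    patient = np.atleast_2d(np.asarray(patient, dtype=float).T).T
    healthy = np.atleast_2d(np.asarray(healthy, dtype=float).T).T
    if patient.ndim == 1:
        patient, healthy = patient[:, None], healthy[:, None]
    rows = []
    for i, vec in enumerate(patient):
        rows.append({"id": f"p{i}", "group": "patient", "age": 70.0,
                     **dict(zip(columns, vec))})
    for i, vec in enumerate(healthy):
        rows.append({"id": f"h{i}", "group": "control", "age": 35.0,
                     **dict(zip(columns, vec))})
    return pd.DataFrame(rows).set_index("id")


class TestSilverman:
    def test_one_dimensional_formula(self):
        assert silverman_bandwidth(1.0, 2) == pytest.approx(1.06 * 2 ** (-0.2))

    def test_linear_in_sd(self):
        assert silverman_bandwidth(2.0, 50) == pytest.approx(
            2 * silverman_bandwidth(1.0, 50)
        )

    def test_multivariate_formula(self):
        d, n, sd = 3, 40, 1.5
        expected = (4.0 / (d + 2)) ** (1 / (d + 4)) * n ** (-1 / (d + 4)) * sd
        assert silverman_bandwidth(sd, n, d) == pytest.approx(expected)

    def test_degenerate_sd_raises(self):
        with pytest.raises(DegenerateBandwidthError):
            silverman_bandwidth(0.0, 10)


class TestKde:
    def test_requires_two_samples_and_spread(self):
        with pytest.raises(ValueError):
            kde_fit(np.array([1.0]))
        with pytest.raises(DegenerateBandwidthError):
            kde_fit(np.array([0.0, 0.0]))

    def test_1d_density_integrates_to_one(self):
        rng = np.random.default_rng(101)
        f = kde_fit(rng.standard_normal(500))
        grid = np.linspace(-6, 6, 4001)
        integral = np.trapezoid(f(grid[:, None]), grid)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_2d_density_integrates_to_one(self):
        rng = np.random.default_rng(202)
        f = kde_fit(rng.standard_normal((300, 2)))
        g = np.linspace(-6, 6, 301)
        xx, yy = np.meshgrid(g, g)
        vals = f(np.column_stack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
        integral = np.trapezoid(np.trapezoid(vals, g, axis=1), g)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_multivariate_path_reduces_to_1d_formula(self):
        """At d=1 the product-kernel evaluation equals the classic single
        variable Gaussian KDE sum evaluated directly."""
        rng = np.random.default_rng(33)
        x = rng.standard_normal(40)
        f = kde_fit(x)
        h = silverman_bandwidth(float(np.std(x, ddof=1)), len(x), d=1)
        grid = np.linspace(-3, 3, 101)
        direct = np.array([
            np.mean(norm.pdf((g - x) / h)) / h for g in grid
        ])
        np.testing.assert_allclose(f(grid[:, None]), direct, atol=1e-12)

    def test_symmetric_samples_peak_at_center(self):
        f = kde_fit(np.array([-2.0, 2.0]))
        grid = np.linspace(-5, 5, 1001)[:, None]
        assert abs(grid[np.argmax(f(grid))][0]) <= 0.01

    def test_density_strictly_positive(self):
        f = kde_fit(np.array([0.0, 1.0, 2.0]))
        assert f(np.array([[10.0]]))[0] > 0  # far into the tail, before underflow


class TestBayesRule:
    def test_higher_patient_density_labels_patient(self):
        f_p = kde_fit(np.array([4.0, 5.0, 6.0]))
        f_h = kde_fit(np.array([-6.0, -5.0, -4.0]))
        assert bayes_classify(np.array([5.0]), f_p, f_h) == "patient"
        assert bayes_classify(np.array([-5.0]), f_p, f_h) == "healthy"

    def test_exact_tie_goes_healthy(self):
        f = kde_fit(np.array([-1.0, 1.0]))
        assert bayes_classify(np.array([0.0]), f, f) == "healthy"

    def test_dimension_mismatch_rejected(self):
        f1 = kde_fit(np.array([0.0, 1.0]))
        f2 = kde_fit(np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError):
            bayes_classify(np.array([0.0]), f1, f2)


class TestRoc:
    def test_endpoints_and_range(self):
        rng = np.random.default_rng(9)
        scores = rng.standard_normal(40)
        labels = (rng.random(40) < 0.5).astype(int)
        points, auc = roc_curve(scores, labels)
        assert tuple(points[0]) == (0.0, 0.0)
        assert tuple(points[-1]) == (1.0, 1.0)
        assert 0.0 <= auc <= 1.0

    def test_auc_equals_mann_whitney_statistic(self):
        """Trapezoid AUC of the score ROC equals the rank-sum (probability of
        correct ordering) form of the AUC."""
        rng = np.random.default_rng(77)
        scores = np.round(rng.standard_normal(60), 1)  # induce ties
        labels = (rng.random(60) < 0.4).astype(int)
        _, auc = roc_curve(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)


class TestLoocv:
    def test_confusion_count_arithmetic(self):
        result = EvaluationResult(
            measures=("m",), num_tp=37, num_fn=13, num_tn=47, num_fp=7,
            sensitivity=37 / 50, specificity=47 / 54,
            accuracy=84 / 104, auc=0.8,
            roc_points=np.zeros((2, 2)), scores=np.zeros(104),
            labels=np.zeros(104, dtype=int),
        )
        assert result.sensitivity == pytest.approx(0.740)
        assert result.specificity == pytest.approx(0.870, abs=5e-4)

    def test_perfectly_separated_groups_score_one(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.normal(10, 0.5, 20), rng.normal(-10, 0.5, 20))
        r = loocv_evaluate(m, ["m1"])
        assert (r.sensitivity, r.specificity, r.accuracy, r.auc) == (1, 1, 1, 1)
        assert r.num_tp + r.num_fn + r.num_tn + r.num_fp == 40

    def test_identical_groups_score_near_chance(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.standard_normal(30), rng.standard_normal(30))
        r = loocv_evaluate(m, ["m1"])
        half_width = 1.96 * np.sqrt(0.25 / 60)
        assert abs(r.accuracy - 0.5) <= half_width

    def test_bayes_consistency_on_shifted_normals(self):
        """N(0,1) vs N(2,1), 200 per group: LOOCV accuracy approaches the
        analytic Bayes accuracy Phi(1) ~ 0.841."""
        rng = np.random.default_rng(314)
        m = _matrix(rng.normal(2.0, 1.0, 200), rng.normal(0.0, 1.0, 200))
        r = loocv_evaluate(m, ["m1"])
        assert r.accuracy == pytest.approx(norm.cdf(1.0), abs=0.05)

    def test_noise_measure_cannot_inflate_accuracy(self):
        """Appending a pure-noise dimension to an informative one must not
        raise LOOCV accuracy beyond binomial noise (leakage guard)."""
        rng = np.random.default_rng(55)
        n = 60
        informative = np.concatenate([rng.normal(2, 1, n), rng.normal(-2, 1, n)])
        noise = rng.standard_normal(2 * n)
        m = _matrix(
            np.column_stack([informative[:n], noise[:n]]),
            np.column_stack([informative[n:], noise[n:]]),
            columns=("signal", "noise"),
        )
        base = loocv_evaluate(m, ["signal"]).accuracy
        joint = loocv_evaluate(m, ["signal", "noise"]).accuracy
        assert joint <= base + 1.96 * np.sqrt(0.25 / (2 * n))

    def test_zero_variance_fold_is_jittered_not_fatal(self):
        patient = np.full(10, 1.0)
        patient[0] = 1.5  # held-out leaves a constant training fold
        healthy = np.linspace(-3, -1, 10)
        m = _matrix(patient, healthy)
        r = loocv_evaluate(m, ["m1"])
        assert r.accuracy > 0.9


class TestSearch:
    def _informative_matrix(self):
        rng = np.random.default_rng(808)
        n = 20
        cols = ("a", "b", "c")
        pat = np.column_stack([
            rng.normal(3, 1, n),       # a: carries all the signal
            rng.standard_normal(n),    # b, c: noise
            rng.standard_normal(n),
        ])
        hea = np.column_stack([
            rng.normal(-3, 1, n),
            rng.standard_normal(n),
            rng.standard_normal(n),
        ])
        return _matrix(pat, hea, columns=cols)

    def test_pairwise_search_over_nine_candidates_yields_36(self):
        import itertools

        names = [f"x{i}" for i in range(9)]
        assert len(list(itertools.combinations(names, 2))) == 36
        rng = np.random.default_rng(12)
        pat = rng.normal(1, 1, (12, 9))
        hea = rng.normal(-1, 1, (12, 9))
        m = _matrix(pat, hea, columns=names)
        results = search_combinations(m, names, d_max=2, sizes=(2,))
        assert len(results) == 36

    def test_subset_counts_up_to_full_depth(self):
        rng = np.random.default_rng(21)
        names = ("a", "b", "c")
        m = _matrix(rng.normal(1, 1, (8, 3)), rng.normal(-1, 1, (8, 3)),
                    columns=names)
        results = search_combinations(m, names, d_max=3)
        assert len(results) == 2**3 - 1

    def test_top_singleton_is_the_informative_measure(self):
        m = self._informative_matrix()
        results = search_combinations(m, ("a", "b", "c"), d_max=1)
        assert results[0].measures == ("a",)

    def test_ranking_is_by_accuracy_then_auc(self):
        m = self._informative_matrix()
        results = search_combinations(m, ("a", "b", "c"), d_max=2)
        keys = [(r.accuracy, r.auc) for r in results]
        assert keys == sorted(keys, reverse=True)
        table = results_table(results)
        assert list(table.columns) == [
            "measures", "n_measures", "sensitivity", "specificity",
            "accuracy", "auc",
        ]
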