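"""Differentiation statistics: test selection, univariate calibration, PCA
against a brute-force eigen oracle, loading factors, contributor selection,
unidirectional attribution, ROC against pair concordance."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from plasmanmr.regions import RegionDefinition, RegionMatrix
from plasmanmr.stats import (
    clinical_association,
    overall_loading_factors,
    roc_analysis,
    run_pca,
    select_contributors,
    select_univariate_test,
    unidirectional_metabolites,
    univariate_compare,
)


def make_matrix(values: np.ndarray, sample_ids=None) -> RegionMatrix:
    n, p = values.shape
    ids = sample_ids or [f"S{i}" for i in range(n)]
    regions = [RegionDefinition(j, 0.5 + 0.1 * j, 0.58 + 0.1 * j)
               for j in range(p)]
    frame = pd.DataFrame(values, index=ids, columns=[r.label for r in regions])
    return RegionMatrix(sample_ids=ids, regions=regions, values=frame)


def two_group_matrix(a: np.ndarray, b: np.ndarray):
    values = np.vstack([a, b])
    ids = [f"A{i}" for i in range(a.shape[0])] + [f"B{i}" for i in range(b.shape[0])]
    m = make_matrix(values, ids)
    labels = pd.Series(["AD"] * a.shape[0] + ["non-AD"] * b.shape[0], index=ids)
    return m, labels


class TestSelectUnivariateTest:
    def test_normal_equal_variance_student_t(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 16)
        b = rng.normal(0.3, 1, 19)
        assert select_univariate_test(a, b) == "student_t"

    def test_normal_unequal_variance_welch(self):
        rng = np.random.default_rng(3)
        for _ in range(20):  # pick a draw failing the variance gate
            a = rng.normal(0, 1, 30)
            b = rng.normal(0, math.sqrt(10), 30)
            if scipy.stats.levene(a, b, center="median").pvalue < 0.05 and \
               scipy.stats.shapiro(a).pvalue >= 0.05 and \
               scipy.stats.shapiro(b).pvalue >= 0.05:
                assert select_univariate_test(a, b) == "welch"
                return
        pytest.fail("no qualifying draw found")

    def test_heavy_skew_kruskal(self):
        rng = np.random.default_rng(5)
        a = np.exp(rng.normal(0, 1.5, 30))  # log-normal, heavy skew
        b = rng.normal(0, 1, 30)
        assert select_univariate_test(a, b) == "kruskal_wallis"

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            select_univariate_test(np.ones(2), np.zeros(5))


class TestUnivariateCompare:
    def test_type_one_error_calibrated(self):
        # identical distributions: p < 0.05 in 5% +/- 2% of 1000 regions
        rng = np.random.default_rng(42)
        n_regions, hits = 1000, 0
        a = rng.normal(0, 1, size=(16, n_regions))
        b = rng.normal(0, 1, size=(19, n_regions))
        m, labels = two_group_matrix(a.T @ np.eye(16) if False else a, b)
        out = univariate_compare(m, labels)
        hits = (out.p_value < 0.05).sum()
        assert abs(hits / n_regions - 0.05) <= 0.02

    def test_power_at_effect_two(self):
        # standardized effect 2.0 at n = 16/19: p < 0.05 in >= 95% of runs
        rng = np.random.default_rng(7)
        hits, n_rep = 0, 200
        a = rng.normal(2.0, 1, size=(16, n_rep))
        b = rng.normal(0.0, 1, size=(19, n_rep))
        m, labels = two_group_matrix(a, b)
        out = univariate_compare(m, labels)
        hits = (out.p_value < 0.05).sum()
        assert hits / n_rep >= 0.95

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(10, 5))
        b = rng.normal(0.5, 1, size=(12, 5))
        m, labels = two_group_matrix(a, b)
        swapped = labels.map({"AD": "non-AD", "non-AD": "AD"})
        p1 = univariate_compare(m, labels).set_index("region_id").p_value
        p2 = univariate_compare(m, swapped).set_index("region_id").p_value
        pd.testing.assert_series_equal(p1, p2)

    def test_degenerate_region_flagged_p_one(self):
        a = np.hstack([np.full((8, 1), 0.3), np.random.default_rng(0).normal(size=(8, 1))])
        b = np.hstack([np.full((8, 1), 0.3), np.random.default_rng(1).normal(size=(8, 1))])
        m, labels = two_group_matrix(a, b)
        out = univariate_compare(m, labels).set_index("region_id")
        assert out.loc[0, "degenerate"]
        assert out.loc[0, "p_value"] == 1.0

    def test_results_sorted_by_p(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, size=(10, 6))
        a[:, 2] += 3.0
        b = rng.normal(0, 1, size=(10, 6))
        m, labels = two_group_matrix(a, b)
        out = univariate_compare(m, labels)
        assert out.p_value.is_monotonic_increasing
        assert out.iloc[0].region_id == 2


class TestClinicalAssociation:
    def metadata(self, ids, score_values, score="mmse"):
        return pd.DataFrame({
            "sample_id": ids,
            "group": ["AD"] * len(ids),
            "is_pooled": [False] * len(ids),
            "cdr_global": [0.5] * len(ids),
            "cdr_sob": [1.0] * len(ids),
            "mmse": [20] * len(ids),
        }).assign(**{score: score_values})

    def test_linear_slope_sign_recovery(self):
        rng = np.random.default_rng(8)
        hits, n_rep = 0, 100
        for _ in range(n_rep):
            n = 35
            mmse = rng.uniform(10, 30, n)
            region = 0.01 * mmse + rng.normal(0, 0.01 * mmse.std() * 4 / 3, n)
            m = make_matrix(region.reshape(-1, 1))
            meta = self.metadata(m.sample_ids, mmse)
            out = clinical_association(m, meta, "mmse")
            if out.iloc[0].slope > 0:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_shuffled_scores_give_uniform_p(self):
        rng = np.random.default_rng(9)
        ps = []
        n = 35
        region = rng.normal(0, 1, n)
        m = make_matrix(region.reshape(-1, 1))
        for _ in range(200):
            mmse = rng.permutation(np.linspace(5, 30, n))
            meta = self.metadata(m.sample_ids, mmse)
            ps.append(clinical_association(m, meta, "mmse").iloc[0].p_value)
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_cdr_groups_identical_values_p_one(self):
        n = 12
        m = make_matrix(np.full((n, 1), 0.4))
        meta = self.metadata(m.sample_ids, [0.0, 0.5, 1.0] * 4, score="cdr_global")
        out = clinical_association(m, meta, "cdr_global")
        assert out.iloc[0].p_value == 1.0

    def test_missing_scores_raise(self):
        n = 10
        m = make_matrix(np.random.default_rng(0).normal(size=(n, 2)))
        vals = [20.0] * 5 + [np.nan] * 5
        meta = self.metadata(m.sample_ids, vals)
        with pytest.raises(ValueError):
            clinical_association(m, meta, "mmse")


class TestRunPCA:
    def brute_force(self, x: np.ndarray):
        """Eigen-decomposition of the correlation matrix as oracle."""
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        corr = z.T @ z / (x.shape[0] - 1)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        return evals[order], evecs[:, order]

    def test_matches_eigen_oracle_on_toy_table(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, size=(5, 4))
        m = make_matrix(x)
        res = run_pca(m)
        evals, evecs = self.brute_force(x)
        k = res.loading_coefficients.shape[1]
        frac = evals[:k] / evals.sum()
        np.testing.assert_allclose(res.explained_variance_fraction, frac[:k],
                                   atol=1e-8)
        for j in range(k):
            v = res.loading_coefficients.iloc[:, j].to_numpy()
            w = evecs[:, j]
            if np.dot(v, w) < 0:
                w = -w
            np.testing.assert_allclose(v, w, atol=1e-8)

    def test_loadings_orthonormal_and_scores_centered(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.uniform(size=(12, 6)))
        res = run_pca(m)
        l = res.loading_coefficients.to_numpy()
        np.testing.assert_allclose(l.T @ l, np.eye(l.shape[1]), atol=1e-9)
        np.testing.assert_allclose(res.scores.mean(0), 0, atol=1e-9)
        assert np.all(np.diff(res.explained_variance_fraction) <= 1e-12)

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.uniform(size=(5, 4)))
        res = run_pca(m)  # components = min(n-1, p) = 4
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicating_samples_leaves_loadings_unchanged(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(size=(6, 4))
        m1 = make_matrix(x)
        m2 = make_matrix(np.vstack([x, x]),
                         [f"S{i}" for i in range(12)])
        l1 = run_pca(m1).loading_coefficients.to_numpy()
        l2 = run_pca(m2).loading_coefficients.to_numpy()
        np.testing.assert_allclose(l1, l2[:, :l1.shape[1]], atol=1e-8)

    def test_zero_variance_region_aborts_with_name(self):
        x = np.random.default_rng(0).uniform(size=(6, 3))
        x[:, 1] = 0.5
        m = make_matrix(x)
        with pytest.raises(ValueError, match=m.regions[1].label):
            run_pca(m)


class TestLoadingFactors:
    def test_hand_arithmetic(self):
        # coefficient 0.30, mean 0.020, SD 0.005 -> factor 1.2
        rng = np.random.default_rng(3)
        m = make_matrix(rng.uniform(size=(8, 4)))
        pca = run_pca(m)
        out = overall_loading_factors(pca, m, 1)
        pca.loading_coefficients.iloc[0, 0] = 0.30
        sub = m.values
        sub.iloc[:, 0] = 0.020 + 0.005 * ((sub.iloc[:, 0] - sub.iloc[:, 0].mean())
                                          / sub.iloc[:, 0].std(ddof=1))
        out = overall_loading_factors(pca, m, 1)
        assert out.iloc[0].overall_loading_factor == pytest.approx(1.2, rel=1e-9)

    def test_zero_coefficient_zero_factor(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.uniform(size=(8, 3)))
        pca = run_pca(m)
        pca.loading_coefficients.iloc[2, 0] = 0.0
        out = overall_loading_factors(pca, m, 1)
        assert out.iloc[2].overall_loading_factor == 0.0

    def test_negating_loadings_negates_factors(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.uniform(size=(8, 3)))
        pca = run_pca(m)
        base = overall_loading_factors(pca, m, 1).overall_loading_factor
        pca.loading_coefficients.iloc[:, 0] *= -1
        flipped = overall_loading_factors(pca, m, 1).overall_loading_factor
        np.testing.assert_allclose(flipped, -base, rtol=1e-12)

    def test_independent_straight_line_oracle(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.uniform(size=(10, 5)))
        pca = run_pca(m)
        out = overall_loading_factors(pca, m, 2)
        for j in range(5):
            coeff = pca.loading_coefficients.iloc[j, 1]
            col = m.values.iloc[:, j]
            expect = coeff * col.mean() / col.std(ddof=1)
            assert out.iloc[j].overall_loading_factor == pytest.approx(
                expect, rel=1e-12)


class TestSelectContributors:
    def table(self, factors):
        return pd.DataFrame({
            "region_id": range(len(factors)),
            "overall_loading_factor": factors,
        })

    def test_hand_enumeration(self):
        pos, neg = select_contributors(self.table([5.0, 3.0, 1.0, -2.0, -4.0, -6.0]))
        assert pos == [0, 1]   # factors 5 and 3
        assert neg == [5, 4]   # factors -6 and -4

    def test_all_positive_empty_negative(self):
        pos, neg = select_contributors(self.table([1.0, 2.0]))
        assert neg == []
        assert len(pos) == 1

    def test_single_positive_selected(self):
        pos, neg = select_contributors(self.table([0.7]))
        assert pos == [0]  # ceil(0.5 * 1) = 1

    def test_zero_factors_in_neither_set(self):
        pos, neg = select_contributors(self.table([0.0, 2.0, -1.0]))
        assert 0 not in pos and 0 not in neg

    def test_tie_break_by_region_id(self):
        pos, _ = select_contributors(self.table([2.0, 2.0, 2.0]))
        assert pos == [0, 1]


class TestUnidirectional:
    def test_shared_metabolite_excluded(self):
        ann = {0: ("glucose", "lactate"), 1: ("lactate",)}
        ad, non = unidirectional_metabolites([0], [1], ann)
        assert ad == ["glucose"] and non == []

    def test_disjoint_annotations_pass_through(self):
        ann = {0: ("a", "b"), 1: ("c",)}
        ad, non = unidirectional_metabolites([0], [1], ann)
        assert ad == ["a", "b"] and non == ["c"]

    def test_toy_mapping_matches_brute_force(self):
        ann = {0: ("m1", "m2"), 1: ("m2", "m3"), 2: ("m4",), 3: ("m3", "m5")}
        pos, neg = [0, 1], [2, 3]
        ad, non = unidirectional_metabolites(pos, neg, ann)
        pos_union = set().union(*(ann[r] for r in pos))
        neg_union = set().union(*(ann[r] for r in neg))
        both = pos_union & neg_union
        assert set(ad) == pos_union - both
        assert set(non) == neg_union - both


def auc_by_pair_concordance(scores, labels, positive):
    """Brute-force Mann-Whitney AUC: fraction of concordant (pos, neg) pairs
    with ties counting one half."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        res = roc_analysis(np.array([0.1, 0.2, 0.8, 0.9]),
                           np.array([0, 0, 1, 1]), positive_label=1)
        assert res.auc == 1.0
        assert res.accuracy == 1.0

    def test_spec_example_matches_pair_concordance(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        res = roc_analysis(scores, labels, positive_label=1)
        assert res.auc == pytest.approx(
            auc_by_pair_concordance(scores, labels, 1))

    @pytest.mark.parametrize("seed", range(8))
    def test_random_inputs_match_pair_concordance(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=30), 1)  # rounded: forces ties
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = roc_analysis(scores, labels, positive_label=1)
        truth = auc_by_pair_concordance(scores, labels, 1)
        assert res.auc == pytest.approx(max(truth, 1 - truth), abs=1e-12)

    def test_permutation_null_centered_at_half(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=35)
        aucs = []
        for _ in range(1000):
            labels = np.zeros(35, dtype=int)
            labels[rng.choice(35, 16, replace=False)] = 1
            aucs.append(auc_by_pair_concordance(scores, labels, 1))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(2)
        res = roc_analysis(rng.normal(size=40), rng.integers(0, 2, 40),
                           positive_label=1)
        assert tuple(res.curve[0]) == (0.0, 0.0)
        assert tuple(res.curve[-1]) == (1.0, 1.0)
        assert np.all(np.diff(res.curve[:, 0]) >= 0)
        assert np.all(np.diff(res.curve[:, 1]) >= 0)
        assert res.auc >= 0.5

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(21)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        res = roc_analysis(scores, labels, positive_label=1)
        ref = roc_auc_score(labels, scores)
        assert res.auc == pytest.approx(max(ref, 1 - ref), abs=1e-12)

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            roc_analysis(np.ones(5), np.ones(5))

    def test_accuracy_at_youden_threshold(self):
        scores = np.array([0.1, 0.2, 0.3, 0.6, 0.7, 0.8])
        labels = np.array([0, 0, 1, 1, 1, 1])
        res = roc_analysis(scores, labels, positive_label=1)
        predicted = (scores >= res.threshold).astype(int)
        assert res.accuracy == pytest.approx((predicted == labels).mean())
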