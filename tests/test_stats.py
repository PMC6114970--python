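import itertools
import math

import numpy as np
import pandas as pd
import pytest

import metabopanel as mp
from metabopanel import stats as st


# ------------------------------------------------------ log transform

class TestLogTransform:
    def test_log_identity_and_base(self):
        df = pd.DataFrame({"x": [1.0, math.e, np.nan]})
        out = st.log_transform(df)
        assert out["x"].iloc[0] == 0.0
        assert out["x"].iloc[1] == pytest.approx(1.0)
        assert np.isnan(out["x"].iloc[2])  # mask preserved

    def test_nonpositive_values_raise_citing_lod_policy(self):
        with pytest.raises(ValueError, match="LOD"):
            st.log_transform(pd.DataFrame({"x": [1.0, 0.0]}))


# ---------------------------------------------------------------- BH

def bh_oracle(pvals):
    """Brute-force BH: sort, p*m/rank, running min from the tail."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBenjaminiHochberg:
    def test_worked_example_all_adjust_to_largest(self):
        adj = st.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_single_pvalue_unchanged(self):
        assert st.benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_matches_exhaustive_oracle_on_short_vectors(self):
        grid = [0.001, 0.01, 0.04, 0.2, 0.5, 0.9]
        for m in range(1, 6):
            for combo in itertools.combinations_with_replacement(grid, m):
                got = st.benjamini_hochberg(list(combo))
                want = bh_oracle(list(combo))
                assert np.allclose(got, want), combo

    def test_null_screen_yields_few_discoveries(self, rng):
        n, m = 40, 1000
        X = pd.DataFrame(rng.normal(size=(n, m)))
        labels = np.array(["a"] * 20 + ["b"] * 20)
        res = st.univariate_screen(X, labels)
        assert (res["fdr"] < 0.05).sum() <= 5


# ----------------------------------------------------------- screens

class TestUnivariateScreen:
    def test_two_groups_uses_welch_more_uses_anova(self, rng):
        X = pd.DataFrame({"f": np.r_[rng.normal(0, 1, 20),
                                     rng.normal(3, 1, 20)]})
        res2 = st.univariate_screen(X, ["a"] * 20 + ["b"] * 20)
        assert res2.loc["f", "p"] < 1e-6
        res3 = st.univariate_screen(X, ["a"] * 14 + ["b"] * 13 + ["c"] * 13)
        assert np.isfinite(res3.loc["f", "p"])

    def test_zero_variance_reports_p_one_with_note(self):
        X = pd.DataFrame({"f": [1.0] * 10})
        res = st.univariate_screen(X, ["a"] * 5 + ["b"] * 5)
        assert res.loc["f", "p"] == 1.0
        assert "zero variance" in res.loc["f", "note"]

    def test_excessive_missingness_skipped_with_note(self):
        X = pd.DataFrame({"f": [1.0, np.nan, np.nan, np.nan]})
        res = st.univariate_screen(X, ["a", "a", "b", "b"])
        assert "missing" in res.loc["f", "note"]


class TestPearson:
    def test_self_and_anti_correlation(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"same": x, "neg": -x})
        res = st.pearson_correlations(X, x)
        assert res.loc["same", "r"] == pytest.approx(1.0)
        assert res.loc["neg", "r"] == pytest.approx(-1.0)

    def test_toy_five_points_match_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        r_direct = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        res = st.pearson_correlations(pd.DataFrame({"f": y}), x)
        assert res.loc["f", "r"] == pytest.approx(r_direct)

    def test_constant_feature_undefined_with_reason(self):
        res = st.pearson_correlations(pd.DataFrame({"f": [1.0] * 5}),
                                      np.arange(5.0))
        assert np.isnan(res.loc["f", "r"])
        assert "constant" in res.loc["f", "note"]


# ---------------------------------------------------------------- ROC

def auc_brute_force(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_four_point_toy_auc_075(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        roc = st.roc_auc(scores, labels)
        assert roc.auc == pytest.approx(0.75)
        assert roc.auc == pytest.approx(auc_brute_force(scores, labels))

    def test_perfect_separation_and_all_ties(self):
        assert st.roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0
        assert st.roc_auc([1, 1, 1, 1], [0, 0, 1, 1]).auc == 0.5

    def test_midrank_matches_brute_force_with_ties(self, rng):
        for _ in range(20):
            scores = rng.integers(0, 5, 30).astype(float)
            labels = rng.integers(0, 2, 30)
            if labels.sum() in (0, 30):
                continue
            assert st.roc_auc(scores, labels).auc == pytest.approx(
                auc_brute_force(scores, labels))

    def test_complement_identity(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        a = st.roc_auc(scores, labels).auc
        b = st.roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_invariance_to_monotone_transforms(self, rng):
        scores = rng.lognormal(0, 1, 60)
        labels = rng.integers(0, 2, 60)
        labels[0], labels[1] = 0, 1
        base = st.roc_auc(scores, labels).auc
        assert st.roc_auc(np.log(scores), labels).auc == pytest.approx(base)
        assert st.roc_auc(3 * scores + 7, labels).auc == pytest.approx(base)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        roc = st.roc_auc(scores, labels)
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
        assert np.trapezoid(roc.tpr, roc.fpr) == pytest.approx(roc.auc)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            st.roc_auc([1.0, 2.0], [1, 1])


class TestOperatingPoint:
    def test_toy_confusion_all_point_75(self):
        # unique Youden maximum with confusion TP=3 FN=1 TN=3 FP=1
        scores = [0.9, 0.8, 0.7, 0.2, 0.85, 0.3, 0.28, 0.26]
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        roc = st.roc_auc(scores, labels)
        op = st.operating_point(roc, labels, scores)
        assert (op.sensitivity, op.specificity, op.ppv, op.npv) == \
            (0.75, 0.75, 0.75, 0.75)

    def test_sensitivity_plus_fnr_is_one(self, rng):
        scores = rng.normal(size=40)
        labels = (scores + rng.normal(0, 1, 40) > 0).astype(int)
        labels[0], labels[1] = 0, 1
        roc = st.roc_auc(scores, labels)
        op = st.operating_point(roc, labels, scores)
        pred = np.asarray(scores) >= op.threshold
        fnr = (~pred & (labels == 1)).sum() / (labels == 1).sum()
        assert op.sensitivity + fnr == pytest.approx(1.0)

    def test_everything_positive_gives_ppv_equal_prevalence(self):
        scores = [1.0, 1.0, 1.0, 1.0]
        labels = [1, 1, 1, 0]
        roc = st.roc_auc(scores, labels)
        op = st.operating_point(roc, labels, scores)
        if op.ppv == op.ppv and (np.asarray(scores) >= op.threshold).all():
            assert op.ppv == pytest.approx(0.75)


# --------------------------------------------------------------- MCCV

def _sep_data(rng, n=30, gap=8.0):
    X = pd.DataFrame({
        "f1": np.r_[rng.normal(0, 1, n), rng.normal(gap, 1, n)],
        "f2": np.r_[rng.normal(0, 1, n), rng.normal(gap, 1, n)],
    })
    y = np.r_[np.zeros(n, int), np.ones(n, int)]
    return X, y


class TestMCCV:
    def test_widely_separated_classes_near_perfect(self, rng):
        X, y = _sep_data(rng)
        res = st.mccv_evaluate(X, y, st.MCCVConfig(n_iterations=30, seed=0))
        assert res.mean_accuracy > 0.99 and res.mean_auc > 0.99

    def test_shuffled_labels_auc_near_half(self, rng):
        X, y = _sep_data(rng, n=40)
        y = rng.permutation(y)
        res = st.mccv_evaluate(X, y, st.MCCVConfig(n_iterations=50, seed=1))
        assert abs(res.mean_auc - 0.5) < 0.1

    def test_same_seed_reproduces_result_exactly(self, rng):
        X, y = _sep_data(rng)
        cfg = st.MCCVConfig(n_iterations=10, seed=5)
        r1 = st.mccv_evaluate(X, y, cfg)
        r2 = st.mccv_evaluate(X, y, cfg)
        assert r1.per_iteration_auc == r2.per_iteration_auc
        assert np.array_equal(r1.pooled_scores, r2.pooled_scores)

    def test_iteration_count_and_mean_identities(self, rng):
        X, y = _sep_data(rng)
        res = st.mccv_evaluate(X, y, st.MCCVConfig(n_iterations=7, seed=2))
        assert len(res.per_iteration_auc) == 7
        assert res.mean_auc == pytest.approx(np.mean(res.per_iteration_auc))

    def test_tiny_class_rejected(self, rng):
        X = pd.DataFrame({"f": rng.normal(size=5)})
        with pytest.raises(ValueError, match="3 samples"):
            st.mccv_evaluate(X, [0, 0, 0, 1, 1],
                             st.MCCVConfig(n_iterations=2, seed=0))

    def test_plsda_option_runs(self, rng):
        X, y = _sep_data(rng)
        res = st.mccv_evaluate(
            X, y, st.MCCVConfig(n_iterations=5, classifier="plsda", seed=0))
        assert res.mean_auc > 0.99


class TestPermutation:
    def test_counting_convention_when_observed_beats_all(self, rng):
        X, y = _sep_data(rng, n=12)
        cfg = st.MCCVConfig(n_iterations=5, seed=3)
        res = st.permutation_test(X, y, cfg, n_perm=19)
        assert res.p_value == pytest.approx((sum(
            1 for v in res.null_stats if v >= res.observed_stat) + 1) / 20)
        assert res.p_value <= 0.1  # separable data: few null wins

    def test_p_in_unit_interval_and_seeded(self, rng):
        X, y = _sep_data(rng, n=10, gap=0.0)
        cfg = st.MCCVConfig(n_iterations=4, seed=9)
        r1 = st.permutation_test(X, y, cfg, n_perm=9)
        r2 = st.permutation_test(X, y, cfg, n_perm=9)
        assert 0 < r1.p_value <= 1
        assert r1.p_value == r2.p_value

    def test_invalid_n_perm_rejected(self, rng):
        X, y = _sep_data(rng, n=10)
        with pytest.raises(ValueError):
            st.permutation_test(X, y, st.MCCVConfig(seed=0), n_perm=0)


class TestBootstrap:
    def test_perfect_separation_gives_degenerate_interval(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = [0, 0, 0, 1, 1, 1]
        lo, hi = st.bootstrap_auc_ci(scores, labels, n_boot=50, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_same_seed_same_interval(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        i1 = st.bootstrap_auc_ci(scores, labels, n_boot=100, seed=4)
        i2 = st.bootstrap_auc_ci(scores, labels, n_boot=100, seed=4)
        assert i1 == i2

    def test_interval_brackets_point_estimate_typically(self, rng):
        hits = 0
        for trial in range(25):
            n = 40
            y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
            s = rng.normal(size=n) + y * 1.0
            auc = st.roc_auc(s, y).auc
            lo, hi = st.bootstrap_auc_ci(s, y, n_boot=200, seed=trial)
            hits += lo <= auc <= hi
        assert hits >= 24


class TestLogistic:
    def test_reference_model_probability_half_at_6_8(self):
        m = st.LAC_PYR_REFERENCE_MODEL
        assert m.predict_proba(6.8) == pytest.approx(0.5, abs=1e-3)
        assert m.predict_proba(-m.intercept / m.slope) == pytest.approx(0.5)

    def test_odds_ratio_is_exp_slope(self):
        assert st.LAC_PYR_REFERENCE_MODEL.odds_ratio == pytest.approx(
            math.exp(1.80))

    @pytest.mark.parametrize("n, tol", [(500, 0.35), (5000, 0.10)])
    def test_parameter_recovery_from_simulated_data(self, n, tol):
        rng = np.random.default_rng(123)
        b0, b1 = -2.0, 0.8
        x = rng.normal(2.5, 1.5, n)
        p = 1 / (1 + np.exp(-(b0 + b1 * x)))
        y = rng.random(n) < p
        fit = st.fit_univariate_logistic(x, y.astype(int))
        assert fit.slope == pytest.approx(b1, rel=tol)
        assert fit.intercept == pytest.approx(b0, rel=tol)

    def test_perfect_separation_warns_and_returns_penalized(self):
        x = np.r_[np.zeros(10), np.ones(10) * 10]
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        with pytest.warns(UserWarning, match="separation|convergence"):
            fit = st.fit_univariate_logistic(x, y)
        assert fit.diagnostics["penalized"]
        assert fit.slope > 0


class TestClustering:
    def test_two_separated_groups_recovered_by_cutting_tree(self, rng):
        X = pd.DataFrame(np.r_[rng.normal(0, 1, (15, 4)),
                               rng.normal(10, 1, (15, 4))])
        hc = st.hierarchical_cluster(X)
        from scipy.cluster.hierarchy import fcluster

        two = fcluster(hc.linkage, 2, criterion="maxclust")
        assert len(set(two[:15])) == 1 and len(set(two[15:])) == 1
        assert two[0] != two[-1]

    def test_duplicated_sample_merges_at_zero_height(self, rng):
        X = rng.normal(size=(5, 3))
        X = np.vstack([X, X[0]])
        hc = st.hierarchical_cluster(pd.DataFrame(X))
        assert hc.linkage[0, 2] == pytest.approx(0.0)

    def test_row_permutation_changes_only_leaf_identities(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 3)),
                         index=[f"s{i}" for i in range(12)])
        perm = rng.permutation(12)
        h1 = st.hierarchical_cluster(X)
        h2 = st.hierarchical_cluster(X.iloc[perm])
        o1 = [h1.sample_ids[i] for i in h1.leaf_order]
        o2 = [h2.sample_ids[i] for i in h2.leaf_order]
        assert set(o1) == set(o2)
        assert sorted(h1.linkage[:, 2]) == pytest.approx(
            sorted(h2.linkage[:, 2]))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            st.hierarchical_cluster(pd.DataFrame([[1.0, 2.0]]))
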