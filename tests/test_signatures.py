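import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from explantkit.normalization import CountMatrix, normalize_counts
from explantkit.signatures import (
    DEResult,
    differential_expression,
    derive_signature,
    ges_score,
    hierarchical_cluster,
    intersect_with_panel,
    km_logrank,
    pca_loading_select,
    roc_youden,
    select_significant,
    spearman_correlate,
    zscore_matrix,
)
from explantkit.synthetic import SurvivalRecord, generate_survival


def count_matrix(values, genes=None, hk=None):
    genes = genes or [f"G{i}" for i in range(len(values))]
    df = pd.DataFrame(np.asarray(values, dtype=float), index=genes,
                      columns=[f"c{j}" for j in range(len(values[0]))])
    cm = CountMatrix(raw=df, housekeeping=tuple(hk or ()))
    cm.normalized = df.astype(float)
    return cm


def nb_counts(rng, mu, alpha, size):
    return rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu), size=size)


class TestDifferentialExpression:
    def test_exact_doubling(self):
        cm = count_matrix([[10, 10, 20, 20], [5, 5, 5, 5]])
        with pytest.warns(UserWarning, match="zero residual variance"):
            de = differential_expression(cm, ["c0", "c1"], ["c2", "c3"], pseudocount=0)
        assert de.table.loc["G0", "log2_fc"] == pytest.approx(1.0)

    def test_identical_groups(self):
        cm = count_matrix([[7, 9, 7, 9]])
        de = differential_expression(cm, ["c0", "c1"], ["c2", "c3"], pseudocount=0)
        assert de.table.loc["G0", "log2_fc"] == 0.0
        assert de.table.loc["G0", "p_value"] == pytest.approx(1.0)

    def test_zero_variance_gene(self):
        cm = count_matrix([[4, 4, 8, 8]])
        with pytest.warns(UserWarning, match="zero residual variance"):
            de = differential_expression(cm, ["c0", "c1"], ["c2", "c3"], pseudocount=0)
        assert de.table.loc["G0", "p_value"] == 0.0

    def test_type_i_error_null_nb_genes(self, rng):
        n_genes, n_per_group, alpha = 2000, 10, 0.05
        counts = nb_counts(rng, 200.0, 0.05, (n_genes, 2 * n_per_group))
        cm = count_matrix(counts)
        cols = cm.columns
        de = differential_expression(cm, cols[:n_per_group], cols[n_per_group:])
        frac = float((de.table["p_value"] < alpha).mean())
        se = np.sqrt(alpha * (1 - alpha) / n_genes)
        assert abs(frac - alpha) < 3 * se

    def test_wald_matches_two_sample_t(self, rng):
        # the group-indicator OLS Wald test is the pooled-variance t-test
        from scipy.stats import ttest_ind

        counts = nb_counts(rng, 300.0, 0.05, (20, 12))
        cm = count_matrix(counts)
        de = differential_expression(cm, cm.columns[:6], cm.columns[6:])
        x = np.log2(cm.normalized + 0.5)
        for g in cm.genes[:5]:
            t, p = ttest_ind(x.loc[g][6:], x.loc[g][:6], equal_var=True)
            assert de.table.loc[g, "wald"] == pytest.approx(t, abs=1e-9)
            assert de.table.loc[g, "p_value"] == pytest.approx(p, abs=1e-9)

    def test_requires_two_columns_per_group(self):
        cm = count_matrix([[1, 2, 3]])
        with pytest.raises(ValueError, match="2 columns"):
            differential_expression(cm, ["c0"], ["c1", "c2"])


class TestSelectSignificant:
    def test_all_half(self):
        de = DEResult(pd.DataFrame({"p_value": [0.5, 0.5]}, index=["A", "B"]))
        assert select_significant(de) == []

    def test_strict_inequality(self):
        de = DEResult(
            pd.DataFrame({"p_value": [0.04, 0.05, 0.06]}, index=["A", "B", "C"])
        )
        assert select_significant(de) == ["A"]

    def test_filter_oracle(self, rng):
        p = rng.uniform(size=200)
        genes = [f"G{i}" for i in range(200)]
        de = DEResult(pd.DataFrame({"p_value": p}, index=genes))
        expected = [g for g, pv in zip(genes, p) if pv < 0.05]
        assert select_significant(de) == expected


class TestPcaLoadingSelect:
    def test_rank_one_structure(self, rng):
        factor = rng.normal(size=30)
        expr = pd.DataFrame(
            np.outer(np.ones(10), factor) * rng.uniform(0.5, 2.0, size=(10, 1)),
            index=[f"G{i}" for i in range(10)],
        )
        selected, loadings, explained = pca_loading_select(expr)
        assert selected == list(expr.index)
        np.testing.assert_allclose(np.abs(loadings), 1.0, atol=1e-9)
        assert explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_selects_nearly_nothing(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 400)),
                            index=[f"G{i}" for i in range(10)])
        selected, _, _ = pca_loading_select(expr)
        assert len(selected) <= 1

    def test_loadings_match_eigendecomposition_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(size=(8, 40)),
                            index=[f"G{i}" for i in range(8)])
        _, loadings, explained = pca_loading_select(expr, loading_threshold=0.0)
        R = np.corrcoef(expr.to_numpy())
        w, V = np.linalg.eigh(R)
        idx = np.argmax(w)
        expected = V[:, idx] * np.sqrt(w[idx])
        if expected.sum() < 0:
            expected = -expected
        np.testing.assert_allclose(loadings.to_numpy(), expected, atol=1e-9)
        assert explained[0] == pytest.approx(w[idx] / w.sum(), abs=1e-9)

    def test_constant_gene_excluded_with_warning(self, rng):
        expr = pd.DataFrame(rng.normal(size=(4, 20)), index=list("ABCD"))
        expr.loc["B"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            _, loadings, _ = pca_loading_select(expr)
        assert "B" not in loadings.index


class TestIntersectWithPanel:
    def test_order_preserving(self):
        assert intersect_with_panel(["A", "B", "C"], ["B", "C", "D"]) == ["B", "C"]

    def test_disjoint_warns(self):
        with pytest.warns(UserWarning, match="disjoint"):
            assert intersect_with_panel(["A"], ["B"]) == []

    def test_case_insensitive_and_deduplicated(self):
        assert intersect_with_panel(["Abc", "ABC", "xyz"], ["abc"]) == ["Abc"]

    def test_set_semantics_oracle(self, rng):
        pool = [f"G{i}" for i in range(30)]
        genes = list(rng.choice(pool, size=20, replace=True))
        panel = list(rng.choice(pool, size=15, replace=False))
        result = intersect_with_panel(genes, panel)
        seen = set()
        expected = []
        for g in genes:
            if g.upper() not in seen:
                seen.add(g.upper())
                if g.upper() in {p.upper() for p in panel}:
                    expected.append(g)
        assert result == expected


class TestGesScore:
    def test_analytic_example(self):
        cm = count_matrix([[4], [16]])
        assert ges_score(cm, ["G0", "G1"], pseudocount=0).iloc[0] == pytest.approx(3.0)

    def test_doubling_adds_one(self, rng):
        counts = rng.integers(1, 1000, size=(10, 6)).astype(float)
        cm = count_matrix(counts)
        doubled = count_matrix(counts * 2)
        a = ges_score(cm, cm.genes[:5], pseudocount=0)
        b = ges_score(doubled, cm.genes[:5], pseudocount=0)
        np.testing.assert_allclose(b - a, 1.0, atol=1e-12)

    def test_mean_of_logs_oracle(self, rng):
        counts = rng.integers(1, 500, size=(12, 4)).astype(float)
        cm = count_matrix(counts)
        genes = list(rng.choice(cm.genes, size=5, replace=False))
        scores = ges_score(cm, genes, pseudocount=0.5)
        expected = np.log2(cm.normalized.loc[genes] + 0.5).mean(axis=0)
        np.testing.assert_allclose(scores, expected, atol=1e-12)

    def test_missing_gene_listed(self):
        cm = count_matrix([[1], [2]])
        with pytest.raises(KeyError, match="XYZ"):
            ges_score(cm, ["G0", "XYZ"])

    def test_monotone_in_gene_count(self):
        cm = count_matrix([[4], [16]])
        low = ges_score(cm, ["G0", "G1"], pseudocount=0).iloc[0]
        cm2 = count_matrix([[8], [16]])
        assert ges_score(cm2, ["G0", "G1"], pseudocount=0).iloc[0] > low


def brute_force_youden(scores, labels):
    """Exhaustive-threshold oracle for the Youden cutoff."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    uniq = np.unique(scores)
    best_num, best_t = -1, None
    for t in (uniq[:-1] + uniq[1:]) / 2:
        tp = int(np.sum(scores[labels == 1] > t))
        tn = int(np.sum(scores[labels == 0] <= t))
        num = tp * n0 + tn * n1  # J on the common denominator (exact)
        if num > best_num:
            best_num, best_t = num, t
    if best_t is None:
        return None, None
    return best_t, best_num / (n0 * n1) - 1.0


class TestRocYouden:
    def test_perfect_separation(self):
        r = roc_youden([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.youden_cutoff == 2.5
        assert r.youden_j == 1.0

    def test_all_tied_scores(self):
        r = roc_youden([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.auc == 0.5
        assert r.youden_j == 0.0

    def test_brute_force_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            r = roc_youden(scores, labels)
            t, j = brute_force_youden(scores, labels)
            if t is None:
                assert np.isnan(r.youden_cutoff)
            else:
                assert r.youden_cutoff == t
                assert r.youden_j == pytest.approx(j, abs=1e-12)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        labels[0], labels[1] = 0, 1
        r = roc_youden(scores, labels)
        assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(st.floats(0.1, 5.0), st.floats(-10.0, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, scale, shift):
        rng = np.random.default_rng(99)
        scores = rng.normal(size=60)
        labels = (scores + rng.normal(0, 1, 60) > 0).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = roc_youden(scores, labels)
        b = roc_youden(scale * scores + shift, labels)  # strictly increasing
        assert b.auc == pytest.approx(a.auc, abs=1e-12)
        # the split each cutoff induces is identical
        assert np.array_equal(scores > a.youden_cutoff,
                              scale * scores + shift > b.youden_cutoff)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both label classes"):
            roc_youden([1, 2, 3], [1, 1, 1])


class TestKmLogrank:
    @staticmethod
    def records(times, events, scores):
        return [SurvivalRecord(f"p{i}", t, e, s)
                for i, (t, e, s) in enumerate(zip(times, events, scores))]

    def test_identical_groups(self):
        recs = self.records([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1],
                            [0, 0, 0, 10, 10, 10])
        km = km_logrank(recs, 5.0)
        assert km.chi_square == pytest.approx(0.0, abs=1e-12)
        assert km.p_value == pytest.approx(1.0)

    def test_four_subject_hand_computed_oracle(self):
        # low group (score<=c): events at t=1, 3; high: events at t=2, 4
        recs = self.records([1.0, 3.0, 2.0, 4.0], [1, 1, 1, 1], [0, 0, 10, 10])
        km = km_logrank(recs, 5.0)
        # hand computation of observed-vs-expected for the high group:
        # t=1: n=4, n_high=2, d=1, d_high=0, e=0.5, v=1*(2/4)*(2/4)*(3/3)=0.25
        # t=2: n=3, n_high=2, d=1, d_high=1, e=2/3, v=(2/3)*(1/3)*(1/1)... d(n1/n)(n2/n)(n-d)/(n-1)=1*(2/3)*(1/3)*(2/2)=2/9
        # t=3: n=2, n_high=1, d=1, d_high=0, e=0.5, v=1*(1/2)*(1/2)*(1/1)=0.25
        # t=4: n=1, n_high=1, d=1, d_high=1, e=1, v=0 (n=1 skipped)
        o_minus_e = (0 - 0.5) + (1 - 2 / 3) + (0 - 0.5) + (1 - 1)
        var = 0.25 + 2 / 9 + 0.25
        assert km.chi_square == pytest.approx(o_minus_e**2 / var, abs=1e-9)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        scores = rng.normal(size=80)
        recs = generate_survival(scores, hazard_slope=0.8, censor_rate=0.2,
                                 max_followup=40, seed=5)
        cutoff = float(np.median(scores))
        km = km_logrank(recs, cutoff)
        t = np.array([r.time for r in recs])
        e = np.array([r.event for r in recs])
        hi = np.array([r.score for r in recs]) > cutoff
        res = logrank_test(t[hi], t[~hi], e[hi], e[~hi])
        assert km.chi_square == pytest.approx(res.test_statistic, abs=1e-9)
        assert km.p_value == pytest.approx(res.p_value, abs=1e-9)

    def test_km_curve_product_limit(self):
        recs = self.records([1, 2, 2, 3], [1, 1, 0, 1], [10, 10, 10, 10] )
        recs += self.records([5], [1], [0])
        km = km_logrank(recs, 5.0)
        curve = km.curves["high"]
        # S(1)=3/4; S(2)=3/4 * (1 - 1/3)=1/2; S(3)=1/2*(1-1/1)=0
        np.testing.assert_allclose(curve["survival"], [0.75, 0.5, 0.0])

    def test_zero_event_group_warns(self):
        recs = self.records([1, 2, 3, 4], [1, 1, 0, 0], [0, 0, 10, 10])
        with pytest.warns(UserWarning, match="zero events"):
            km = km_logrank(recs, 5.0)
        assert np.isfinite(km.chi_square)

    def test_empty_group_rejected(self):
        recs = self.records([1, 2], [1, 1], [1, 2])
        with pytest.raises(ValueError, match="empty"):
            km_logrank(recs, 10.0)

    def test_power_on_simulated_effect(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            scores = rng.normal(6, 1, 300)
            recs = generate_survival(scores, hazard_slope=1.0, censor_rate=0.1,
                                     max_followup=60, seed=2000 + rep)
            km = km_logrank(recs, float(np.median(scores)))
            hits += km.p_value < 0.05
        assert hits >= 95

    def test_null_p_uniform(self):
        pvals = []
        for rep in range(500):
            rng = np.random.default_rng(rep)
            scores = rng.normal(0, 1, 80)
            recs = generate_survival(scores, hazard_slope=0.0, censor_rate=0.2,
                                     max_followup=60, seed=10_000 + rep)
            km = km_logrank(recs, float(np.median(scores)))
            pvals.append(km.p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestZscoreMatrix:
    def test_simple_row(self):
        z = zscore_matrix(pd.DataFrame([[1.0, 2.0, 3.0]]))
        sd = np.std([1, 2, 3])
        np.testing.assert_allclose(z.to_numpy()[0], [-1 / sd, 0, 1 / sd])

    def test_constant_row_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_matrix(pd.DataFrame([[5.0, 5.0, 5.0]]))
        np.testing.assert_array_equal(z.to_numpy(), 0.0)

    def test_rows_standardized(self, rng):
        z = zscore_matrix(pd.DataFrame(rng.normal(2, 3, size=(20, 15))))
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-12)


class TestHierarchicalCluster:
    def test_duplicates_merge_first(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]],
                          index=["a", "b", "c"])
        Z, order = hierarchical_cluster(df, axis="rows")
        assert Z[0, 2] == 0.0  # first merge at distance 0
        assert abs(order.index("a") - order.index("b")) == 1  # leaves adjacent

    def test_collinear_points(self):
        df = pd.DataFrame([[0.0], [1.0], [10.0]], index=["x", "y", "z"])
        Z, order = hierarchical_cluster(df, axis="rows")
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}  # (0,1) merge precedes 10

    def test_distances_match_brute_force(self, rng):
        from scipy.spatial.distance import pdist

        df = pd.DataFrame(rng.normal(size=(6, 4)))
        Z, _ = hierarchical_cluster(df, axis="rows")
        d = pdist(df.to_numpy())
        assert Z[0, 2] == pytest.approx(d.min())


class TestSpearmanCorrelate:
    def test_monotone_pairs(self):
        params = pd.DataFrame({"up": [1, 2, 3, 4, 5], "down": [5, 4, 3, 2, 1]},
                              index=list("abcde"))
        ges = pd.Series([10, 20, 30, 40, 50], index=list("abcde"))
        out = spearman_correlate(params, ges)
        assert out.loc["up", "rho"] == pytest.approx(1.0)
        assert out.loc["down", "rho"] == pytest.approx(-1.0)

    def test_exact_permutation_oracle_n6(self, rng):
        x = rng.normal(size=6)
        g = rng.normal(size=6)
        params = pd.DataFrame({"x": x}, index=list("abcdef"))
        ges = pd.Series(g, index=list("abcdef"))
        out = spearman_correlate(params, ges)
        # exhaustive permutation distribution of rho
        from scipy.stats import rankdata

        rx, rg = rankdata(x), rankdata(g)
        rho_obs = np.corrcoef(rx, rg)[0, 1]
        count, total = 0, 0
        for perm in itertools.permutations(range(6)):
            rho = np.corrcoef(rx, rg[list(perm)])[0, 1]
            total += 1
            count += abs(rho) >= abs(rho_obs) - 1e-12
        assert out.loc["x", "p_value"] == pytest.approx(count / total, abs=1e-12)

    def test_constant_vector_missing(self):
        params = pd.DataFrame({"c": [1.0] * 5}, index=list("abcde"))
        ges = pd.Series([1, 2, 3, 4, 5.0], index=list("abcde"))
        with pytest.warns(UserWarning, match="constant"):
            out = spearman_correlate(params, ges)
        assert np.isnan(out.loc["c", "rho"])

    def test_minimum_pairs(self):
        params = pd.DataFrame({"x": [1, 2]}, index=["a", "b"])
        ges = pd.Series([1, 2], index=["a", "b"])
        with pytest.raises(ValueError, match="at least 4"):
            spearman_correlate(params, ges)


class TestDerivationChain:
    def test_planted_block_recovery(self):
        n_genes, block, n_per_group = 750, 20, 12
        sens_all, false_rates = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mu = rng.lognormal(np.log(150), 1.0, size=n_genes)
            mu_mat = np.tile(mu[:, None], (1, 2 * n_per_group))
            mu_mat[:block, n_per_group:] *= 2.0  # planted 2x effect
            counts = nb_counts(rng, mu_mat, 0.05, mu_mat.shape)
            cm = count_matrix(counts)
            cols = cm.columns
            sig = derive_signature(cm, cols[:n_per_group], cols[n_per_group:])
            planted = set(cm.genes[:block])
            got = set(sig.genes)
            sens_all.append(len(got & planted) / block)
            false_rates.append(len(got - planted) / max(1, len(got)))
        assert np.mean(sens_all) >= 0.8
        assert np.mean(false_rates) <= 0.05

    def test_signature_scores_orientation(self, cohort_nocells):
        cohort = cohort_nocells
        cm = normalize_counts(cohort.counts)
        sc1 = [s.counts_column_id("Control") for s in cohort if s.true_class == "R"]
        sc2d = [s.counts_column_id("Control") for s in cohort if s.true_class == "NR"]
        sig = derive_signature(cm, sc2d, sc1, name="baseline")
        assert len(sig.genes) >= 5
        roc = roc_youden(sig.scores.loc[sc2d + sc1],
                         [0] * len(sc2d) + [1] * len(sc1))
        assert roc.auc >= 0.9
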