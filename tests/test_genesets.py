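"""ssGSEA against a brute-force oracle, rank-invariance properties, marker
means, and score correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tlsig import (CohortSpec, ExpressionMatrix, TLS_SIGNATURE_GENES,
                   ValidationError, compare_score_by_group,
                   compute_tls_score, marker_mean_score, score_correlation,
                   simulate_cohort, ssgsea_score, stratify_by_quartile)


def brute_force_ssgsea(values: np.ndarray, genes, in_set, alpha):
    """Independent running-sum implementation: explicit loop over the ranked
    gene list accumulating the weighted in-set CDF minus the out-of-set CDF."""
    ranks = stats.rankdata(values)
    order = sorted(range(len(genes)), key=lambda i: (-ranks[i], i))
    in_flags = [genes[i] in in_set for i in order]
    w_total = sum(ranks[i] ** alpha for i in order if genes[i] in in_set)
    n_out = sum(1 for f in in_flags if not f)
    es = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for pos, i in enumerate(order):
        if in_flags[pos]:
            cum_in += ranks[i] ** alpha / w_total
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


def matrix(arr, genes, samples, scale="linear"):
    return ExpressionMatrix(
        pd.DataFrame(arr, index=pd.Index(genes, name="gene_id"),
                     columns=samples),
        scale=scale,
    )


class TestSSGSEA:
    @pytest.mark.parametrize("alpha", [0.25, 1.0])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, alpha, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(5)]
        vals = rng.uniform(0, 10, (5, 3))
        em = matrix(vals, genes, ["s1", "s2", "s3"])
        in_set = {"g1", "g3"}
        table = ssgsea_score(em, {"S": sorted(in_set)}, alpha=alpha)
        for j, s in enumerate(["s1", "s2", "s3"]):
            expected = brute_force_ssgsea(vals[:, j], genes, in_set, alpha)
            assert table.scores.loc[s, "S"] == pytest.approx(
                expected, abs=1e-10)

    def test_top2_set_on_5_gene_matrix(self):
        genes = [f"g{i}" for i in range(5)]
        vals = np.array([[5.0], [4.0], [3.0], [2.0], [1.0]])
        em = matrix(vals, genes, ["s"])
        got = ssgsea_score(em, {"top": ["g0", "g1"]}, alpha=0.25)
        expected = brute_force_ssgsea(vals[:, 0], genes, {"g0", "g1"}, 0.25)
        assert got.scores.loc["s", "top"] == pytest.approx(expected,
                                                           abs=1e-10)

    def test_identical_samples_get_identical_scores(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(0, 10, 8)
        em = matrix(np.column_stack([col, col]),
                    [f"g{i}" for i in range(8)], ["s1", "s2"])
        t = ssgsea_score(em, {"S": ["g0", "g5"]})
        assert t.scores.loc["s1", "S"] == t.scores.loc["s2", "S"]

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0.1, 10, (20, 2))
        genes = [f"g{i}" for i in range(20)]
        sets = {"S": ["g2", "g7", "g11"]}
        t1 = ssgsea_score(matrix(vals, genes, ["a", "b"]), sets)
        t2 = ssgsea_score(matrix(np.exp(vals), genes, ["a", "b"]), sets)
        t3 = ssgsea_score(matrix(vals + 5.0, genes, ["a", "b"]), sets)
        pd.testing.assert_frame_equal(t1.scores, t2.scores)
        pd.testing.assert_frame_equal(t1.scores, t3.scores)

    def test_permutation_null_mean_matches_analytic_expectation(self):
        # The rank-weighted running sum is NOT mean-zero under random sets:
        # in-set steps are weighted by rank^alpha, so the weighted in-set CDF
        # stochastically dominates the uniform out-of-set CDF. The null mean
        # is E[ES] ~ sum_i (C_i/C_G - i/G) with C_i the cumulative
        # rank-weight; the permutation mean must match this value, not zero.
        rng = np.random.default_rng(4)
        G, k, alpha = 200, 20, 0.25
        genes = [f"g{i}" for i in range(G)]
        vals = rng.uniform(0, 100, G)
        gene_set = {"S": [f"g{i}" for i in rng.choice(G, k,
                                                      replace=False)]}
        es = []
        for _ in range(500):
            perm = rng.permutation(vals)
            t = ssgsea_score(matrix(perm[:, None], genes, ["s"]), gene_set,
                             alpha=alpha)
            es.append(t.scores.loc["s", "S"])
        es = np.array(es)
        r = np.arange(G, 0, -1, dtype=float)  # rank value by list position
        C = np.cumsum(r**alpha)
        expected = np.sum(C / C[-1] - np.arange(1, G + 1) / G)
        assert es.mean() == pytest.approx(expected,
                                          abs=3 * es.std() / np.sqrt(500))

    def test_degenerate_sets_rejected(self):
        em = matrix(np.ones((3, 1)), ["a", "b", "c"], ["s"])
        with pytest.raises(ValidationError, match="no genes"):
            ssgsea_score(em, {"S": ["zz"]})
        with pytest.raises(ValidationError, match="every expressed gene"):
            ssgsea_score(em, {"S": ["a", "b", "c"]})


class TestMarkerMean:
    def test_log_scale_markers_average_directly(self):
        em = matrix(np.full((3, 2), 3.0), ["a", "b", "c"], ["s1", "s2"],
                    scale="log2p1")
        t = marker_mean_score(em, {"S": ["a", "b"]})
        assert np.allclose(t.scores["S"], 3.0)

    def test_singleton_set_is_identity(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 9, (4, 3))
        em = matrix(vals, list("abcd"), ["s1", "s2", "s3"])
        t = marker_mean_score(em, {"only_b": ["b"]})
        np.testing.assert_allclose(t.scores["only_b"],
                                   np.log2(vals[1] + 1.0))

    def test_matches_tls_score_on_signature(self, default_cohort,
                                            default_scores):
        t = marker_mean_score(default_cohort.expression,
                              {"TLS": list(TLS_SIGNATURE_GENES)})
        pd.testing.assert_series_equal(t.scores["TLS"],
                                       default_scores.series("TLS"))

    def test_covarying_marker_set_separates_tls_strata(self):
        # plant a 5-gene "exhausted T" set that co-varies with the latent
        # factor by treating it as part of the generator's signature
        spec = CohortSpec(
            n_samples=300, n_genes=60,
            signature_genes=tuple(list(TLS_SIGNATURE_GENES)
                                  + [f"TEX{i}" for i in range(5)]),
            seed=7,
        )
        cohort = simulate_cohort(spec)
        tls = compute_tls_score(cohort.expression)
        strata = stratify_by_quartile(tls.series("TLS"), mode="two_class_q3")
        tex = marker_mean_score(cohort.expression,
                                {"TEX": [f"TEX{i}" for i in range(5)]})
        res = compare_score_by_group(tex.scores["TEX"], strata.labels,
                                     test="ranksum")
        assert res["medians"]["hi"] > res["medians"]["low"]
        assert res["p_value"] < 0.01


class TestCorrelation:
    def test_self_correlation_is_one(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]},
                          index=[f"s{i}" for i in range(5)])
        c = score_correlation(df, df, method="pearson")
        assert c.coefficients.loc["x", "x"] == pytest.approx(1.0)

    def test_perfect_anti_rank(self):
        idx = list("abcd")
        a = pd.DataFrame({"x": [1.0, 2, 3, 4]}, index=idx)
        b = pd.DataFrame({"y": [4.0, 3, 2, 1]}, index=idx)
        c = score_correlation(a, b, method="spearman", min_samples=4)
        assert c.coefficients.loc["x", "y"] == pytest.approx(-1.0)

    def test_spearman_formula_with_one_swap(self):
        # d^2 sums to 2: r = 1 - 6*2/(5*24) = 0.9
        idx = list("abcde")
        a = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]}, index=idx)
        b = pd.DataFrame({"y": [1.0, 2, 3, 5, 4]}, index=idx)
        c = score_correlation(a, b, method="spearman")
        assert c.coefficients.loc["x", "y"] == pytest.approx(0.9)

    def test_insufficient_shared_samples_reported_na(self):
        a = pd.DataFrame({"x": [1.0, 2, 3]}, index=list("abc"))
        b = pd.DataFrame({"y": [3.0, 2, 1]}, index=list("abc"))
        c = score_correlation(a, b, min_samples=5)
        assert np.isnan(c.coefficients.loc["x", "y"])

    def test_disjoint_samples_rejected(self):
        a = pd.DataFrame({"x": [1.0]}, index=["a"])
        b = pd.DataFrame({"y": [1.0]}, index=["b"])
        with pytest.raises(ValidationError):
            score_correlation(a, b)
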