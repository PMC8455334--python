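"""Association scans against closed-form and brute-force oracles."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netsig import associate
from netsig.datatypes import ExpressionMatrix, ValidationError


def _frame(rows, samples=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    samples = samples or [f"S{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(rows.shape[0])],
                        columns=samples)


class TestResidualize:
    def test_single_nominal_factor_is_within_group_centring(self):
        # analytic example: values 1..4, groups A,A,B,B -> residuals +-0.5
        data = _frame([[1, 2, 3, 4]])
        cov = pd.DataFrame({"grp": ["A", "A", "B", "B"]}, index=data.columns)
        out = associate.residualize_covariates(data, cov)
        np.testing.assert_allclose(out.data.to_numpy()[0], [-0.5, 0.5, -0.5, 0.5],
                                   atol=1e-12)

    def test_no_covariates_mean_centres(self):
        data = _frame([[2.0, 4.0, 6.0]])
        out = associate.residualize_covariates(data, None)
        np.testing.assert_allclose(out.data.to_numpy()[0], [-2, 0, 2], atol=1e-12)

    def test_residuals_orthogonal_to_design_and_match_normal_equations(self):
        rng = np.random.default_rng(0)
        data = _frame(rng.normal(size=(20, 6)))
        z = rng.normal(size=6)
        cov = pd.DataFrame({"z": z}, index=data.columns)
        out = associate.residualize_covariates(data, cov).data.to_numpy()
        assert np.abs(out @ z).max() < 1e-10
        assert np.abs(out.sum(axis=1)).max() < 1e-10
        # normal-equations oracle
        X = np.column_stack([np.ones(6), z])
        beta = np.linalg.solve(X.T @ X, X.T @ data.to_numpy().T)
        expected = data.to_numpy() - (X @ beta).T
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_aliased_nominal_columns_detected(self):
        data = _frame(np.arange(8, dtype=float).reshape(2, 4))
        cov = pd.DataFrame(
            {"a": ["x", "x", "y", "y"], "b": ["u", "u", "v", "v"]},
            index=data.columns,
        )
        # perfectly aliased factors: second is pruned, result still valid
        out = associate.residualize_covariates(data, cov)
        assert np.isfinite(out.data.to_numpy()).all()


def _exact_perm_p(x, y):
    """Independent oracle: two-sided permutation p of Spearman rho.

    Enumerates all n! orderings of the response ranks; correlation reduces
    to the cross-product sum because rank means/variances are permutation
    invariant (no ties here).
    """
    rx = stats.rankdata(x) - (len(x) + 1) / 2
    ry = stats.rankdata(y) - (len(y) + 1) / 2
    obs = abs(float(rx @ ry))
    count = total = 0
    for perm in permutations(ry):
        count += abs(sum(a * b for a, b in zip(rx, perm))) >= obs - 1e-9
        total += 1
    return count / total


class TestRankRegression:
    def test_monotone_gene_flagged_positive(self):
        rng = np.random.default_rng(1)
        resp = pd.Series(np.arange(10, dtype=float), index=[f"S{i}" for i in range(10)])
        data = _frame([np.arange(10) * 2.0 + 1, rng.normal(size=10)])
        table = associate.rank_regression_scan(data, resp, None, alpha=0.01, exact=False)
        row = table.set_index("feature_id").loc["g0"]
        assert row["sign"] == "+"
        assert row["p"] < 1e-4
        # equals the Spearman t-test for a monotone gene without ties
        sp = stats.spearmanr(data.loc["g0"], resp)
        assert np.isclose(row["p"], sp.pvalue, rtol=1e-6) or row["p"] < sp.pvalue

    def test_constant_gene_degenerate(self):
        resp = pd.Series(np.arange(8, dtype=float), index=[f"S{i}" for i in range(8)])
        data = _frame([np.full(8, 3.0)])
        table = associate.rank_regression_scan(data, resp, None)
        assert table.loc[0, "p"] == 1.0
        assert bool(table.loc[0, "degenerate"])

    def test_exact_mode_matches_permutation_oracle_n8(self):
        rng = np.random.default_rng(2)
        resp = pd.Series(rng.normal(size=8), index=[f"S{i}" for i in range(8)])
        data = _frame(rng.normal(size=(3, 8)))
        table = associate.rank_regression_scan(data, resp, None, exact=True)
        for i in range(3):
            oracle = _exact_perm_p(data.iloc[i].to_numpy(), resp.to_numpy())
            assert abs(table.loc[i, "p"] - oracle) < 1e-9

    def test_covariate_elimination_removes_confounded_signal(self):
        # gene depends on response only through a shared covariate
        rng = np.random.default_rng(3)
        n = 40
        z = rng.normal(size=n)
        resp = pd.Series(2.0 * z + 0.1 * rng.normal(size=n),
                         index=[f"S{i}" for i in range(n)])
        gene = 3.0 * z + 0.1 * rng.normal(size=n)
        data = _frame([gene])
        cov = pd.DataFrame({"z": z}, index=data.columns)
        raw = associate.rank_regression_scan(data, resp, None, exact=False)
        adj = associate.rank_regression_scan(data, resp, cov, exact=False)
        assert raw.loc[0, "p"] < 1e-6
        assert adj.loc[0, "p"] > 0.01

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        data = _frame(rng.normal(size=(5, 12)))
        resp = pd.Series(rng.normal(size=12), index=data.columns)
        t1 = associate.rank_regression_scan(data, resp, None, exact=False)
        perm = list(rng.permutation(data.columns))
        t2 = associate.rank_regression_scan(data[perm], resp, None, exact=False)
        np.testing.assert_allclose(t1["p"], t2["p"], atol=1e-12)

    def test_tiny_cohort_refused_without_exact(self):
        data = _frame(np.random.default_rng(5).normal(size=(2, 5)))
        resp = pd.Series(np.arange(5.0), index=data.columns)
        table = associate.rank_regression_scan(data, resp, None)  # auto-exact
        assert (table["p"] <= 1).all()
        with pytest.raises(ValidationError):
            associate.rank_regression_scan(data.iloc[:, :3], resp.iloc[:3], None)


def _kw_oracle(groups):
    """Brute-force rank-sum formula with tie correction."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


class TestKruskalWallis:
    @staticmethod
    def _make_geno(calls_rows, samples):
        from netsig.datatypes import GenotypeMatrix
        calls = pd.DataFrame(calls_rows, columns=samples)
        calls.index = [f"m{i}" for i in range(len(calls_rows))]
        meta = pd.DataFrame(
            {"gene": "GENE1", "chromosome": "1", "ld_block_id": "LD1",
             "pseudoautosomal": False},
            index=calls.index,
        )
        return GenotypeMatrix(calls, meta)

    def test_textbook_three_group_h_statistic(self):
        # AA {1,2}, AB {3,4}, BB {5,6} -> H = 4.571 by the rank-sum formula
        samples = [f"S{i}" for i in range(6)]
        geno = self._make_geno([["AA", "AA", "AB", "AB", "BB", "BB"]], samples)
        resp = pd.Series([1.0, 2, 3, 4, 5, 6], index=samples)
        table = associate.kruskal_wallis_genetic(geno, resp, model="genotypic")
        assert np.isclose(table.loc[0, "statistic"], 4.571, atol=5e-4)
        oracle = _kw_oracle([np.array([1.0, 2]), np.array([3.0, 4]), np.array([5.0, 6])])
        assert np.isclose(table.loc[0, "statistic"], oracle, atol=1e-10)

    def test_equal_responses_give_zero_h(self):
        samples = [f"S{i}" for i in range(6)]
        geno = self._make_geno([["AA", "AA", "AB", "AB", "BB", "BB"]], samples)
        resp = pd.Series(np.ones(6), index=samples)
        table = associate.kruskal_wallis_genetic(geno, resp)
        assert table.loc[0, "statistic"] == 0.0
        assert table.loc[0, "p"] == 1.0

    def test_h_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = int(rng.integers(6, 15))
            samples = [f"S{i}" for i in range(n)]
            codes = rng.choice(["AA", "AB", "BB"], size=n)
            while len(np.unique(codes)) < 2:
                codes = rng.choice(["AA", "AB", "BB"], size=n)
            resp = pd.Series(np.round(rng.normal(size=n), 1), index=samples)
            geno = self._make_geno([list(codes)], samples)
            table = associate.kruskal_wallis_genetic(geno, resp, model="genotypic")
            groups = [resp[codes == c].to_numpy() for c in np.unique(codes)]
            assert np.isclose(table.loc[0, "statistic"], _kw_oracle(groups), atol=1e-9)

    def test_dominant_and_recessive_groupings(self):
        samples = [f"S{i}" for i in range(6)]
        geno = self._make_geno([["AA", "AA", "AB", "AB", "BB", "BB"]], samples)
        resp = pd.Series([1.0, 2, 3, 4, 5, 6], index=samples)
        dom = associate.kruskal_wallis_genetic(geno, resp, model="dominant")
        oracle = _kw_oracle([np.array([1.0, 2]), np.array([3.0, 4, 5, 6])])
        assert np.isclose(dom.loc[0, "statistic"], oracle, atol=1e-10)
        rec = associate.kruskal_wallis_genetic(geno, resp, model="recessive")
        oracle = _kw_oracle([np.array([1.0, 2, 3, 4]), np.array([5.0, 6])])
        assert np.isclose(rec.loc[0, "statistic"], oracle, atol=1e-10)

    def test_single_group_marker_skipped(self):
        samples = [f"S{i}" for i in range(4)]
        geno = self._make_geno([["AA", "AA", "AA", "AA"]], samples)
        resp = pd.Series([1.0, 2, 3, 4], index=samples)
        table = associate.kruskal_wallis_genetic(geno, resp)
        assert bool(table.loc[0, "degenerate"])
        assert "group" in table.loc[0, "skip_reason"]


class TestAdjustments:
    def test_ld_bonferroni_genome_scale(self):
        # p = 1e-4 against 768 LD blocks -> 0.0768 genome-wide
        table = pd.DataFrame({"feature_id": ["m1"], "p": [1e-4]})
        out = associate.adjust_ld_bonferroni(table, {"GENE1": 5}, {"m1": "GENE1"}, 768)
        assert np.isclose(out.loc[0, "p_adj_genome"], 0.0768)
        assert np.isclose(out.loc[0, "p_adj_gene"], 5e-4)

    def test_clipped_at_one_and_identity_for_single_block(self):
        table = pd.DataFrame({"feature_id": ["m1", "m2"], "p": [0.5, 0.01]})
        out = associate.adjust_ld_bonferroni(
            table, {"G": 1}, {"m1": "G", "m2": "G"}, 10
        )
        assert out.loc[0, "p_adj_genome"] == 1.0
        assert out.loc[1, "p_adj_gene"] == 0.01

    def test_missing_annotation_refused(self):
        table = pd.DataFrame({"feature_id": ["m1"], "p": [0.1]})
        with pytest.raises(ValidationError):
            associate.adjust_ld_bonferroni(table, {}, {}, 10)

    def test_bh_step_up_definition(self):
        table = pd.DataFrame({"feature_id": list("abcd"),
                              "p": [0.01, 0.02, 0.03, 0.04]})
        out = associate.adjust_fdr_bh(table)
        np.testing.assert_allclose(out["p_adj"], [0.04, 0.04, 0.04, 0.04])

    def test_bh_single_p_unchanged_and_permutation_invariant(self):
        single = associate.adjust_fdr_bh(pd.DataFrame({"feature_id": ["a"], "p": [0.2]}))
        assert single.loc[0, "p_adj"] == 0.2
        rng = np.random.default_rng(7)
        p = rng.random(50)
        t1 = associate.adjust_fdr_bh(pd.DataFrame({"feature_id": range(50), "p": p}))
        perm = rng.permutation(50)
        t2 = associate.adjust_fdr_bh(
            pd.DataFrame({"feature_id": perm, "p": p[perm]})
        ).set_index("feature_id").loc[t1["feature_id"]]
        np.testing.assert_allclose(t1["p_adj"], t2["p_adj"], atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(8)
        p = rng.random(100)
        out = associate.adjust_fdr_bh(pd.DataFrame({"feature_id": range(100), "p": p}))
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        assert out["p_adj"].between(0, 1).all()


class TestVarianceFilter:
    def test_keep_all_is_identity(self):
        data = _frame(np.random.default_rng(9).normal(size=(10, 5)))
        out = associate.variance_filter(data, n_keep=10)
        pd.testing.assert_frame_equal(out.data, data.sort_index(),
                                      check_names=False)

    def test_high_variance_genes_selected(self):
        rng = np.random.default_rng(10)
        loud = rng.normal(0, 5, size=(5, 20))
        quiet = rng.normal(0, 0.01, size=(95, 20))
        data = _frame(np.vstack([loud, quiet]))
        out = associate.variance_filter(data, n_keep=5)
        assert set(out.data.index) == {f"g{i}" for i in range(5)}

    def test_score_based_mode_brackets_informative_count(self):
        sizes = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n_info = 20
            centres = rng.normal(0, 3, size=(3, n_info))
            labels = rng.integers(0, 3, 30)
            info = centres[labels].T + rng.normal(0, 0.5, size=(n_info, 30))
            noise = rng.normal(0, 0.5, size=(180, 30))
            data = _frame(np.vstack([info, noise]))
            out = associate.variance_filter(data, n_keep=None, n_components=2,
                                            seed=seed, grid=[10, 20, 40, 80, 200])
            sizes.append(out.data.shape[0])
        assert all(20 <= s <= 40 for s in sizes), sizes

    def test_invalid_n_keep(self):
        data = _frame(np.zeros((3, 4)))
        with pytest.raises(ValidationError):
            associate.variance_filter(data, n_keep=0)
        with pytest.raises(ValidationError):
            associate.variance_filter(data, n_keep=10)
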