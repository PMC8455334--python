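"""Quartile labelling, SMOTE, OOB random forest, BORUTA, ordinations."""

import numpy as np
import pandas as pd
import pytest

from netsig import classify
from netsig.datatypes import ValidationError


def _sep_data(n=60, p=10, seed=0, gap=1.0):
    """One perfectly separating feature among noise."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.normal(size=(n, p))
    X[:, 0] = rng.uniform(0, 1, n) + y * (1.0 + gap)  # classes disjoint on f0
    return X, y


class TestQuartileLabels:
    def test_eight_samples_floor_rule(self):
        resp = pd.Series(np.arange(1, 9, dtype=float),
                         index=[f"S{i}" for i in range(8)])
        out = classify.quartile_labels(resp)
        assert list(out.labels[resp.nsmallest(2).index]) == ["low", "low"]
        assert list(out.labels[resp.nlargest(2).index]) == ["high", "high"]
        assert (out.labels == "mid").sum() == 4

    def test_n71_gives_17_per_tail(self):
        resp = pd.Series(np.random.default_rng(0).normal(size=71),
                         index=[f"S{i:02d}" for i in range(71)])
        out = classify.quartile_labels(resp)
        assert (out.labels == "low").sum() == 17
        assert (out.labels == "high").sum() == 17

    def test_all_equal_split_deterministic_by_id(self):
        resp = pd.Series(np.ones(8), index=[f"S{i}" for i in range(8)])
        out1 = classify.quartile_labels(resp)
        out2 = classify.quartile_labels(resp.sample(frac=1, random_state=1))
        assert set(out1.labels[out1.labels == "low"].index) == {"S0", "S1"}
        pd.testing.assert_series_equal(out1.labels.sort_index(),
                                       out2.labels.sort_index())

    def test_small_n_refused(self):
        with pytest.raises(ValidationError):
            classify.quartile_labels(pd.Series(np.arange(5.0)))


class TestSmote:
    def test_balances_minority_to_majority(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 4))
        y = np.array([1] * 5 + [0] * 20)
        Xo, yo = classify.smote_oversample(X, y, k=3, seed=2)
        assert (yo == 0).sum() == 20
        assert (yo == 1).sum() == 20
        np.testing.assert_array_equal(Xo[:25], X)  # originals unchanged

    def test_k1_synthetics_on_the_single_segment(self):
        p, q = np.array([0.0, 0.0]), np.array([1.0, 2.0])
        X = np.vstack([p, q, np.random.default_rng(3).normal(5, 1, (8, 2))])
        y = np.array([1, 1] + [0] * 8)
        Xo, yo = classify.smote_oversample(X, y, k=1, seed=4)
        synth = Xo[10:]
        # every synthetic point is p + u * (q - p)
        u = synth[:, 1] / 2.0
        np.testing.assert_allclose(synth[:, 0], u, atol=1e-12)
        assert ((u >= 0) & (u <= 1)).all()

    def test_synthetics_are_pairwise_convex_combinations(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        y = np.array([1] * 8 + [0] * 22)
        Xo, yo = classify.smote_oversample(X, y, k=5, seed=6)
        minority = X[:8]
        for s in Xo[30:]:
            found = False
            for i in range(8):
                for j in range(8):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    denom = d @ d
                    if denom == 0:
                        continue
                    u = (s - minority[i]) @ d / denom
                    if 0 - 1e-9 <= u <= 1 + 1e-9 and np.allclose(
                        s, minority[i] + u * d, atol=1e-9
                    ):
                        found = True
                        break
                if found:
                    break
            assert found

    def test_minority_of_one_refused(self):
        X = np.zeros((5, 2))
        y = np.array([1, 0, 0, 0, 0])
        with pytest.raises(ValidationError):
            classify.smote_oversample(X, y, seed=0)


class TestRandomForestOOB:
    def test_perfect_feature_low_oob_error_high_auc(self):
        for seed in range(3):
            X, y = _sep_data(n=60, seed=seed)
            rep = classify.rf_classify_oob(X, y, n_trees=300, seed=seed)
            assert rep.oob_error <= 0.05
            assert rep.auc >= 0.98
            assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]
            assert rep.importance.idxmax() == "f0"

    def test_pure_noise_auc_near_half(self):
        aucs = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(100, 20))
            y = rng.permutation([0] * 50 + [1] * 50)
            rep = classify.rf_classify_oob(X, y, n_trees=200, seed=seed)
            aucs.append(rep.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.12

    def test_bit_reproducible_under_fixed_seed(self):
        X, y = _sep_data(n=40, seed=9, gap=0.0)
        r1 = classify.rf_classify_oob(X, y, n_trees=50, seed=7)
        r2 = classify.rf_classify_oob(X, y, n_trees=50, seed=7)
        assert r1.auc == r2.auc
        assert r1.oob_error == r2.oob_error
        pd.testing.assert_series_equal(r1.oob_scores, r2.oob_scores)

    def test_degenerate_inputs_refused(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValidationError):
            classify.rf_classify_oob(X, np.zeros(10, dtype=int), n_trees=5)
        with pytest.raises(ValidationError):
            classify.rf_classify_oob(X, np.array([1] + [0] * 9), n_trees=5)


class TestBoruta:
    def test_planted_feature_confirmed_noise_rejected(self):
        rng = np.random.default_rng(11)
        n, p_noise = 100, 50
        y = rng.permutation([0] * 50 + [1] * 50)
        X = rng.normal(size=(n, p_noise + 1))
        X[:, 0] += 2.0 * y
        out = classify.boruta_select(X, y, n_iter=100, seed=1, n_trees=60)
        assert out.loc[0, "status"] == "confirmed"
        noise = out.iloc[1:]
        assert (noise["status"] == "rejected").mean() >= 0.95
        assert set(out.attrs["shadow"]) == {"max", "mean", "min"}

    def test_all_noise_confirms_nothing(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(80, 20))
        y = rng.permutation([0] * 40 + [1] * 40)
        out = classify.boruta_select(X, y, n_iter=40, seed=2, n_trees=60)
        assert (out["status"] == "confirmed").sum() == 0

    def test_too_few_iterations_refused(self):
        with pytest.raises(ValidationError):
            classify.boruta_select(np.zeros((20, 2)),
                                   np.array([0, 1] * 10), n_iter=5)


class TestPLSDA:
    def test_first_weight_proportional_to_xty(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 8))
        y = rng.permutation([0] * 15 + [1] * 15).astype(float)
        res = classify.pls_da_fit(X, y, n_components=2)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w_closed = Xc.T @ yc
        w_closed /= np.linalg.norm(w_closed)
        w1 = res.weights["comp1"].to_numpy()
        cos = abs(w1 @ w_closed) / np.linalg.norm(w1)
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_axis_shifted_groups_fully_separated(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(40, 5))
        y = np.array([0] * 20 + [1] * 20)
        X[:, 0] += 8.0 * y
        res = classify.pls_da_fit(X, y, n_components=1)
        s = res.scores["comp1"].to_numpy()
        # component-1 scores separate groups completely (sign-invariant)
        assert (s[y == 1].min() > s[y == 0].max()) or (s[y == 1].max() < s[y == 0].min())
        assert res.auc == 1.0

    @pytest.mark.parametrize("n_components", [2, 3])
    def test_component_counts_used_by_the_ordinations(self, n_components):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(25, 12))
        y = rng.permutation([0] * 12 + [1] * 13).astype(float)
        res = classify.pls_da_fit(X, y, n_components=n_components)
        assert res.scores.shape == (25, n_components)

    def test_zero_variance_refused(self):
        with pytest.raises(ValidationError):
            classify.pls_da_fit(np.ones((10, 3)), np.array([0, 1] * 5), 1)


class TestDAPC:
    def test_full_rank_reduces_to_plain_lda(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(16)
        X = rng.normal(size=(30, 4))
        g = np.array([0] * 15 + [1] * 15)
        X[g == 1] += 1.5
        res = classify.dapc_fit(X, g, n_pcs=4)
        plain = LinearDiscriminantAnalysis().fit(X, g).transform(X)[:, 0]
        d = res.discriminants["LD1"].to_numpy()
        r = np.corrcoef(d, plain)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_separated_clusters_fully_reassigned(self):
        rng = np.random.default_rng(17)
        X = np.vstack([rng.normal(0, 1, (20, 6)), rng.normal(8, 1, (20, 6))])
        g = np.array([0] * 20 + [1] * 20)
        res = classify.dapc_fit(X, g, n_pcs=3)
        assert res.accuracy == 1.0

    def test_identical_groups_give_flat_discriminant(self):
        X = np.tile(np.arange(10.0)[:, None], (2, 3))
        g = np.array([0] * 10 + [1] * 10)
        res = classify.dapc_fit(X, g, n_pcs=2)
        between = abs(res.discriminants[g == 0].mean() - res.discriminants[g == 1].mean())
        assert float(between.iloc[0]) < 1e-8

    def test_singleton_group_refused(self):
        with pytest.raises(ValidationError):
            classify.dapc_fit(np.zeros((5, 2)), np.array([0, 0, 0, 0, 1]), n_pcs=2)


class TestPhenotypeComparison:
    def test_clinical_only_strong_when_clinical_explains_all(self, small_world):
        from netsig import simulate

        truth = simulate.default_truth(
            small_world["planted"], seed=20,
            clinical_r2={"GHD": 1.0, "TS": 1.0}, bio_r2=0.0,
        )
        expr, pheno = simulate.generate_cohort(
            truth, small_world["graph"], {"GHD": 200}, 200, seed=21
        )
        sub = pheno.condition("GHD")
        resp = sub.table["hv1"]
        labels = classify.quartile_labels(resp)
        y = labels.task("low")
        clin = sub.clinical_features()
        rep = classify.rf_classify_oob(clin.loc[y.index], y.to_numpy(),
                                       n_trees=500, seed=3)
        assert rep.auc >= 0.95

    def test_sample_mismatch_refused(self):
        clin = pd.DataFrame(np.zeros((4, 2)), index=list("abcd"))
        expr = pd.DataFrame(np.zeros((3, 4)), columns=list("abcd"))
        y = pd.Series([0, 1, 0, 1], index=list("abce"))
        with pytest.raises(ValidationError):
            classify.compare_phenotype_models(clin, expr, y, n_trees=5)

    def test_paired_uplift_test_detects_consistent_gain(self):
        clin = [0.85, 0.87, 0.86, 0.9, 0.84]
        comb = [0.95, 0.93, 0.96, 0.94, 0.92]
        assert classify.paired_uplift_test(clin, comb) < 0.01
        assert classify.paired_uplift_test(clin, clin) == 1.0
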