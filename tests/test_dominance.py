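import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from territory.dominance import (
    BEHAVIOR_COLUMNS,
    DominanceModel,
    assign_ranks,
    behavior_correlations,
    dominance_pca,
    kruskal_dunn,
    preference_index,
    repairing_permutation_test,
    wilcoxon_paired,
    zscore_across_cohort,
)
from territory.synthetic import simulate_behavior_matrix


def toy_matrix(n_pairs=5, seed=0):
    m, truth = simulate_behavior_matrix(n_pairs, 1.0, seed)
    return m, truth


class TestZscore:
    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"attacks": [1.0, 1.0, 1.0], "chases": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="attacks"):
            zscore_across_cohort(df)

    def test_two_value_column_population_convention(self):
        df = pd.DataFrame({"x": [0.0, 2.0]})
        out = zscore_across_cohort(df, ddof=0)
        np.testing.assert_allclose(out["x"], [-1.0, 1.0])

    def test_random_matrix_standardised(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(5, 3, (40, 4)), columns=list("abcd"))
        z = zscore_across_cohort(df)
        assert np.abs(z.mean(axis=0)).max() < 1e-12
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0)

    def test_pooling_across_strains(self):
        # pooled z-scores differ from per-group standardisation
        df = pd.DataFrame({"x": [0.0, 1.0, 10.0, 11.0]})
        z = zscore_across_cohort(df)
        assert z["x"].iloc[0] < -0.8  # far below the pooled mean


class TestDominancePCA:
    def test_anticorrelated_two_behavior_rank_one(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        z = pd.DataFrame({"attacks": x, "hiding": -x})
        _, evr, _ = dominance_pca(z)
        assert evr[0] == pytest.approx(1.0)

    def test_hand_eigen_solve_on_3x2_matrix(self):
        z = pd.DataFrame({"attacks": [1.0, -0.5, -0.5], "flights": [0.5, 0.5, -1.0]})
        zc = z - z.mean(axis=0)
        cov = zc.to_numpy().T @ zc.to_numpy() / (len(z) - 1)
        w, v = np.linalg.eigh(cov)  # ascending
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        load, evr, scores = dominance_pca(z)
        np.testing.assert_allclose(evr, w / w.sum(), atol=1e-12)
        for k in range(2):
            ref = v[:, k] if v[0, k] > 0 else -v[:, k]
            np.testing.assert_allclose(load.iloc[:, k], ref, atol=1e-12)

    def test_variance_fractions_sum_to_one(self):
        m, _ = toy_matrix(8, 3)
        res = DominanceModel(m).fit()
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()

    def test_isotropic_noise_spreads_variance(self):
        rng = np.random.default_rng(1)
        z = pd.DataFrame(rng.normal(size=(2000, 7)), columns=list(BEHAVIOR_COLUMNS))
        _, evr, _ = dominance_pca(zscore_across_cohort(z))
        np.testing.assert_allclose(evr, np.full(7, 1 / 7), atol=0.02)

    def test_attack_loading_oriented_positive(self):
        m, _ = toy_matrix(10, 5)
        res = DominanceModel(m).fit()
        assert res.loadings.loc["attacks", "PC1"] > 0

    def test_row_permutation_invariance(self):
        m, _ = toy_matrix(6, 7)
        res1 = DominanceModel(m).fit()
        perm = m.sample(frac=1.0, random_state=4)
        res2 = DominanceModel(perm).fit()
        s1 = res1.scores.set_index("mouse_id")["PC1"]
        s2 = res2.scores.set_index("mouse_id")["PC1"]
        np.testing.assert_allclose(s1.loc[s2.index], s2, atol=1e-9)

    def test_missing_cells_rejected(self):
        m, _ = toy_matrix(4, 0)
        m.loc[0, "attacks"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            DominanceModel(m).fit()

    def test_summary_mentions_variance_and_pairs(self):
        m, _ = toy_matrix(4, 2)
        text = DominanceModel(m).fit().summary()
        assert "Variance explained" in text and "dominant" in text


class TestAssignRanks:
    def test_higher_pc1_dominant(self):
        scores = pd.DataFrame(
            {"mouse_id": ["a", "b"], "pair_id": ["p", "p"], "PC1": [2.0, -1.5]}
        )
        rk = assign_ranks(scores)
        assert rk.loc[0, "dominant"] == "a"
        assert rk.loc[0, "pc1_difference"] == pytest.approx(3.5)

    def test_exact_tie_flagged(self):
        scores = pd.DataFrame(
            {"mouse_id": ["a", "b"], "pair_id": ["p", "p"], "PC1": [1.0, 1.0]}
        )
        rk = assign_ranks(scores)
        assert bool(rk.loc[0, "tied"]) and rk.loc[0, "dominant"] is None

    def test_planted_dominant_recovered_at_high_divergence(self):
        hits = total = 0
        for seed in range(5):
            m, truth = simulate_behavior_matrix(20, 1.0, 100 + seed)
            res = DominanceModel(m).fit()
            for r in res.ranks.itertuples():
                hits += r.dominant == truth[r.pair_id]
                total += 1
        assert hits / total >= 0.95


def exhaustive_matchings(ids):
    """Independent oracle: recursively enumerate perfect matchings."""
    if not ids:
        return [[]]
    a, rest = ids[0], ids[1:]
    out = []
    for i, b in enumerate(rest):
        rem = rest[:i] + rest[i + 1 :]
        for sub in exhaustive_matchings(rem):
            out.append([(a, b)] + sub)
    return out


class TestRepairingPermutation:
    def test_identical_values_p_one(self):
        vals = {m: 5.0 for m in "abcd"}
        res = repairing_permutation_test(vals, [("a", "b"), ("c", "d")])
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_cohort_of_four_equals_enumeration_oracle(self):
        vals = {"a": 1.0, "b": 4.0, "c": 2.0, "d": 9.0}
        pairs = [("a", "b"), ("c", "d")]
        res = repairing_permutation_test(vals, pairs)
        assert res.exhaustive and res.n_permutations == 3
        stats_oracle = [
            np.mean([abs(vals[x] - vals[y]) for x, y in m])
            for m in exhaustive_matchings(list("abcd"))
        ]
        obs = np.mean([abs(vals[a] - vals[b]) for a, b in pairs])
        p_oracle = np.mean([s >= obs for s in stats_oracle])
        assert sorted(res.null) == sorted(stats_oracle)
        assert res.p_value == pytest.approx(p_oracle)

    def test_cohort_of_six_equals_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        ids = list("abcdef")
        vals = dict(zip(ids, rng.normal(size=6)))
        pairs = [("a", "b"), ("c", "d"), ("e", "f")]
        res = repairing_permutation_test(vals, pairs)
        assert res.exhaustive and res.n_permutations == 15
        stats_oracle = sorted(
            np.mean([abs(vals[x] - vals[y]) for x, y in m])
            for m in exhaustive_matchings(ids)
        )
        np.testing.assert_allclose(sorted(res.null), stats_oracle)

    def test_divergent_pairs_significant(self):
        rng = np.random.default_rng(0)
        vals, pairs = {}, []
        for k in range(10):
            vals[f"p{k}a"] = rng.normal(10, 0.5)
            vals[f"p{k}b"] = rng.normal(0, 0.5)
            pairs.append((f"p{k}a", f"p{k}b"))
        res = repairing_permutation_test(vals, pairs, n_perm=2000, seed=1)
        assert res.p_value <= 0.05

    def test_odd_cohort_rejected(self):
        with pytest.raises(ValueError):
            repairing_permutation_test({"a": 1, "b": 2}, [("a", "b")])

    def test_seeded_reproducible(self):
        rng = np.random.default_rng(2)
        ids = [f"m{k}" for k in range(12)]
        vals = dict(zip(ids, rng.normal(size=12)))
        pairs = [(ids[2 * i], ids[2 * i + 1]) for i in range(6)]
        a = repairing_permutation_test(vals, pairs, n_perm=200, seed=9, exhaustive_limit=1)
        b = repairing_permutation_test(vals, pairs, n_perm=200, seed=9, exhaustive_limit=1)
        np.testing.assert_array_equal(a.null, b.null)


class TestCorrelations:
    def test_self_and_anticorrelation(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": -x, "z": np.random.default_rng(0).normal(size=10)})
        out = behavior_correlations(df)
        assert out["corr"].loc["x", "x"] == 1.0
        assert out["corr"].loc["x", "y"] == pytest.approx(-1.0)

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"x": np.arange(5.0), "c": np.ones(5)})
        out = behavior_correlations(df)
        assert "c" in out["constant"]
        assert np.isnan(out["corr"].loc["x", "c"])
        assert not out["significant"].loc["x", "c"]

    def test_recovers_planted_correlation(self):
        rng = np.random.default_rng(4)
        n, rho = 200, 0.8
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        out = behavior_correlations(pd.DataFrame({"x": x, "y": y}))
        r = out["corr"].loc["x", "y"]
        # Fisher CI around the true value
        se = 1 / np.sqrt(n - 3)
        assert abs(np.arctanh(r) - np.arctanh(rho)) < 3 * se
        assert out["significant"].loc["x", "y"]


class TestStandardTests:
    def test_wilcoxon_degenerate_identical(self):
        out = wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["statistic"] == 0.0 and out["p_value"] == 1.0 and out["degenerate"]

    def test_wilcoxon_matches_scipy(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=15), rng.normal(size=15)
        out = wilcoxon_paired(x, y)
        ref = stats.wilcoxon(x, y)
        assert out["statistic"] == pytest.approx(ref.statistic)
        assert out["p_value"] == pytest.approx(ref.pvalue)

    def test_kruskal_identical_groups_h_near_zero(self):
        g = {"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [1.0, 2, 3]}
        out = kruskal_dunn(g)
        assert out["H"] == pytest.approx(0.0, abs=1e-9)

    def test_kruskal_h_matches_hand_rank_formula(self):
        groups = {"a": [1.0, 3.0, 5.0], "b": [2.0, 4.0, 6.0], "c": [7.0, 8.0, 9.0]}
        pooled = np.concatenate(list(groups.values()))
        ranks = stats.rankdata(pooled)
        N = len(pooled)
        splits = np.split(ranks, [3, 6])
        H_hand = 12 / (N * (N + 1)) * sum(len(r) * r.mean() ** 2 for r in splits) - 3 * (N + 1)
        out = kruskal_dunn(groups)
        assert out["H"] == pytest.approx(H_hand)
        assert len(out["posthoc"]) == 3
        assert ((out["posthoc"]["p_adjusted"] >= out["posthoc"]["p_raw"] - 1e-12)).all()

    def test_dunn_z_hand_computed_two_groups(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}
        out = kruskal_dunn(groups, p_adjust="bonferroni")
        # mean ranks 2 and 5, no ties: se = sqrt((6*7/12)*(1/3+1/3))
        z_hand = (2 - 5) / np.sqrt((6 * 7 / 12) * (2 / 3))
        assert out["posthoc"]["z"].iloc[0] == pytest.approx(z_hand)


class TestPreferenceIndex:
    @pytest.mark.parametrize(
        "ta,tb,expected",
        [(10.0, 10.0, 0.0), (30.0, 10.0, 0.5), (0.0, 20.0, -1.0), (20.0, 0.0, 1.0)],
    )
    def test_values(self, ta, tb, expected):
        assert preference_index(ta, tb) == pytest.approx(expected)

    def test_undefined_when_both_zero(self):
        assert np.isnan(preference_index(0.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            preference_index(-1.0, 5.0)
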