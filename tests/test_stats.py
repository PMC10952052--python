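import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from exobench.stats import (anova_tukey, build_comparison_report,
                            dunn_bonferroni, kruskal_type1_rate,
                            kruskal_wallis, mann_whitney, shapiro_wilk)


def _kruskal_oracle(groups):
    """Direct evaluation of the tie-corrected H formula."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


class TestShapiroWilk:
    def test_normal_quantiles_score_high(self):
        x = sps.norm.ppf(np.linspace(0.01, 0.99, 50))
        w, p = shapiro_wilk(x)
        assert w > 0.98

    def test_bimodal_sample_rejected(self):
        x = np.concatenate([np.full(25, 0.0), np.full(25, 10.0)])
        x += np.linspace(-0.01, 0.01, 50)  # break exact ties
        w, p = shapiro_wilk(x)
        assert w < 0.8
        assert p < 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk(np.ones(10))


class TestKruskalWallis:
    def test_identical_groups_null(self):
        res = kruskal_wallis([[1, 1, 1], [1, 1, 1]])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_matches_hand_ranked_oracle(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(_kruskal_oracle(groups),
                                              rel=1e-12)

    def test_tie_correction_matches_formula(self):
        groups = [[1.0, 2.0, 2.0, 3.0], [2.0, 3.0, 3.0, 5.0],
                  [1.0, 5.0, 5.0, 6.0]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(_kruskal_oracle(groups),
                                              rel=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=8), rng.normal(1.0, size=8),
                  rng.normal(size=8)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


def _dunn_oracle(groups, names):
    """Loop-based Dunn z / Bonferroni evaluation, independent of the
    vectorized implementation."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    means, sizes = [], []
    start = 0
    for g in groups:
        means.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    ties = 0.0
    for v in set(pooled.tolist()):
        t = (pooled == v).sum()
        ties += t**3 - t
    var = n * (n + 1) / 12.0 - ties / (12.0 * (n - 1))
    k = len(groups)
    m = k * (k - 1) / 2
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            z = (means[i] - means[j]) / np.sqrt(
                var * (1 / sizes[i] + 1 / sizes[j]))
            out[(names[i], names[j])] = min(
                1.0, 2 * (1 - sps.norm.cdf(abs(z))) * m)
    return out


class TestDunnBonferroni:
    def test_identical_groups_not_significant(self):
        mat = dunn_bonferroni([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert mat.iloc[0, 1] == pytest.approx(1.0)

    def test_five_groups_yield_ten_pairs(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(loc=i, size=6) for i in range(5)]
        mat = dunn_bonferroni(groups)
        assert mat.shape == (5, 5)
        np.testing.assert_allclose(np.diag(mat.to_numpy()), 1.0)
        # adjustment factor is the number of pairs (10), before clipping
        oracle = _dunn_oracle(groups, list(mat.index))
        for (a, b), p in oracle.items():
            assert mat.loc[a, b] == pytest.approx(p, rel=1e-10)

    def test_matrix_symmetric(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(size=5) for _ in range(4)]
        mat = dunn_bonferroni(groups).to_numpy()
        np.testing.assert_allclose(mat, mat.T)

    def test_bonferroni_never_below_raw(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(loc=i * 0.5, size=7) for i in range(3)]
        adj = dunn_bonferroni(groups)
        raw = _dunn_oracle(groups, list(adj.index))
        for (a, b), p_adj_oracle in raw.items():
            assert adj.loc[a, b] >= p_adj_oracle / 3 - 1e-12


class TestAnovaTukey:
    def test_equal_means_give_near_zero_f(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=10)
        res = anova_tukey([base, base + 0.0, base * 1.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_two_group_f_equals_t_squared(self):
        a = [4.1, 5.2, 6.3, 5.5, 4.9]
        b = [6.8, 7.7, 6.1, 8.0, 7.2]
        res = anova_tukey([a, b])
        t, p_t = sps.ttest_ind(a, b)
        assert res.statistic == pytest.approx(t**2, rel=1e-10)
        assert res.pvalue == pytest.approx(p_t, rel=1e-10)

    def test_matches_brute_force_sums_of_squares(self):
        groups = [np.array([2.0, 3.0, 4.0]), np.array([5.0, 6.0, 7.0]),
                  np.array([1.0, 2.0, 6.0])]
        res = anova_tukey(groups)
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df_b, df_w = 2, 6
        f_expected = (ss_between / df_b) / (ss_within / df_w)
        assert res.statistic == pytest.approx(f_expected, rel=1e-12)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([[1.0, 1.0], [2.0, 2.0]])


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u == 0.0

    def test_identical_multisets_give_half(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, _ = mann_whitney(a, list(a))
        assert u == pytest.approx(len(a) * len(a) / 2)

    def test_exact_p_matches_enumeration(self):
        a = [2.3, 4.5, 1.2, 6.7, 3.3]
        b = [5.1, 7.2, 8.3, 2.9, 6.1]
        u_obs, p = mann_whitney(a, b)
        pooled = np.array(a + b)
        n = len(a)
        u_all = []
        for idx in itertools.combinations(range(len(pooled)), n):
            grp = pooled[list(idx)]
            rest = np.delete(pooled, list(idx))
            u = sum((x > y).sum() for x, y in
                    [(grp[:, None], rest[None, :])])
            u_all.append(u)
        u_all = np.array(u_all, dtype=float)
        # two-sided exact p: tail symmetric around n_a n_b / 2
        mid = n * (len(b))
        dev = np.abs(u_all - mid / 2)
        p_exact = np.mean(dev >= abs(u_obs - mid / 2) - 1e-12)
        assert p == pytest.approx(p_exact, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestTypeOneCalibration:
    def test_null_rejection_rate_near_alpha(self):
        rate = kruskal_type1_rate(n_sims=400, seed=11)
        assert 0.02 <= rate <= 0.09


class TestComparisonReport:
    def _metrics(self, effect=0.0, n_subjects=8, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        conditions = ["no_exo", "rigid_a", "rigid_b", "soft_a", "soft_b"]
        for s in range(n_subjects):
            for cond in conditions:
                for task in ["Squat", "Stoop", "Asymmetric"]:
                    if task == "Squat" and cond == "rigid_b":
                        continue  # hinge-limited device skips squatting
                    for muscle in ["LongLumb", "Ilioc"]:
                        for side in ["L", "R"]:
                            shift = -effect if cond.startswith("rigid") else 0.0
                            rows.append({
                                "subject": f"S{s}", "condition": cond,
                                "task": task, "muscle": muscle, "side": side,
                                "metric": "iemg",
                                "value": 100.0 + shift
                                + rng.normal(scale=3.0)})
        return pd.DataFrame(rows)

    def test_identical_conditions_yield_no_significant_pairs(self):
        report = build_comparison_report(self._metrics(effect=0.0, seed=1))
        n_sig = sum(len(v["significant_pairs"])
                    for v in report["emg"].values())
        # a handful of chance hits are possible; a systematic pattern is not
        assert n_sig <= 2

    def test_large_effect_detected(self):
        report = build_comparison_report(self._metrics(effect=40.0, seed=2))
        keys = [k for k in report["emg"] if "Stoop" in k]
        hits = [v for k in keys
                for v in [report["emg"][k]]
                if ["no_exo", "rigid_a"] in v["significant_pairs"]
                or ["rigid_a", "no_exo"] in v["significant_pairs"]]
        assert hits

    def test_excluded_condition_absent_from_squat_cell(self):
        report = build_comparison_report(self._metrics(seed=3))
        squat_keys = [k for k in report["emg"] if k.startswith("Squat/")]
        assert squat_keys
        for k in squat_keys:
            assert "rigid_b" not in report["emg"][k]["conditions_present"]

    def test_sides_kept_separate_for_asymmetric_only(self):
        report = build_comparison_report(self._metrics(seed=4))
        assert any(k.endswith("_L") for k in report["emg"]
                   if k.startswith("Asymmetric/"))
        assert all(k.endswith("_avg") for k in report["emg"]
                   if k.startswith("Squat/"))

    def test_global_vas_routes(self):
        rng = np.random.default_rng(5)
        gvas = pd.DataFrame({
            "subject": [f"S{i}" for i in range(20)],
            "condition": ["no_exo", "exo_a"] * 10,
            "sex": ["M"] * 10 + ["F"] * 10,
            "vas": rng.normal(3.0, 1.0, 20).clip(0, 10),
        })
        report = build_comparison_report(self._metrics(seed=6),
                                         global_vas=gvas)
        assert "anova" in report["subjective"]["global_vas"]
        assert "U" in report["subjective"]["global_vas_by_sex"]
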