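"""Statistical primitives against independent oracles."""
import itertools

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from hippomorph import stats as hs

rng = np.random.default_rng(2024)


class TestLsSlope:
    def test_two_point_line(self):
        fit = hs.ls_slope([0.0, 52.0], [0.0, 1.0])
        assert fit.slope == pytest.approx(1.0 / 52.0)
        assert fit.slope * 52 == pytest.approx(1.0)

    def test_constant_values(self):
        fit = hs.ls_slope([0, 12, 24, 52, 104], [7.3] * 5)
        assert fit.slope == pytest.approx(0.0, abs=1e-15)
        assert fit.intercept == pytest.approx(7.3)

    def test_normal_equation_oracle(self):
        # times (0,12,24), values (1,2,4): slope = sum(tc*vc)/sum(tc^2) = 36/288
        fit = hs.ls_slope([0, 12, 24], [1, 2, 4])
        assert fit.slope == pytest.approx(0.125)

    def test_undefined_without_two_distinct_times(self):
        with pytest.raises(hs.UndefinedSlopeError):
            hs.ls_slope([10.0, 10.0], [1.0, 2.0])

    def test_vectorized_matches_scalar(self):
        t = np.array([0.0, 12, 24, 52])
        v = rng.normal(size=(4, 7))
        many = hs.ls_slope_many(t, v)
        for j in range(7):
            assert many[j] == pytest.approx(hs.ls_slope(t, v[:, j]).slope)


def enumerate_mwu_p(x, y):
    """Two-sided exact Mann-Whitney p by brute-force relabeling (no ties)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    mean_u = n * len(y) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n):
        r = sps.rankdata(pooled)[list(comb)]
        us.append(r.sum() - n * (n + 1) / 2)
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        r = hs.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0
        assert r.p_value == pytest.approx(0.1)  # 2/20 labelings as extreme

    def test_identical_samples_p_near_one(self):
        r = hs.mann_whitney_u([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert r.p_value > 0.9

    def test_all_identical_values(self):
        assert hs.mann_whitney_u([5.0] * 4, [5.0] * 6).p_value == 1.0

    @pytest.mark.parametrize("n,m", [(n, m) for n in range(1, 9) for m in range(n, 9) if n + m <= 10])
    def test_exact_path_equals_enumeration(self, n, m):
        local = np.random.default_rng(100 * n + m)
        x, y = local.normal(size=n), local.normal(size=m)
        assert hs.mann_whitney_u(x, y).p_value == pytest.approx(enumerate_mwu_p(x, y), abs=1e-12)

    def test_normal_approx_close_to_exact_at_n8(self):
        worst = 0.0
        for rep in range(20):
            local = np.random.default_rng(rep)
            x, y = local.normal(size=8), local.normal(size=8)
            u = hs.mann_whitney_u(x, y).statistic
            exact = hs._exact_two_sided_p(u, 8, 8)
            approx = hs._approx_two_sided_p(u, 8, 8, 0.0, 16)
            worst = max(worst, abs(exact - approx))
        # the tie-free continuity-corrected normal approximation deviates most
        # near mid-range p (~0.44), where it is off by just over 0.01
        assert worst < 0.012

    def test_matches_scipy_with_ties(self):
        x = np.array([1.0, 2, 2, 3, 5, 5, 7, 9, 9, 9, 11])
        y = np.array([2.0, 2, 4, 5, 6, 8, 9, 9, 10, 12])
        mine = hs.mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic", use_continuity=True)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_vectorized_map_matches_scalar(self):
        a = rng.normal(size=(12, 25))
        b = rng.normal(size=(15, 25)) + 0.5
        u, p = hs.mann_whitney_u_map(a, b)
        for j in (0, 7, 24):
            r = hs.mann_whitney_u(a[:, j], b[:, j])
            assert u[j] == pytest.approx(r.statistic)
            assert p[j] == pytest.approx(r.p_value)


def brute_force_bh(p, q):
    """Largest rejection set R = {p <= t} with m*t/|R| <= q (independent
    characterization of the BH step-up)."""
    p = np.asarray(p)
    m = len(p)
    best_t = 0.0
    for t in np.sort(p):
        if m * t / np.sum(p <= t) <= q:
            best_t = max(best_t, t)
    return p <= best_t if best_t > 0 else np.zeros(m, bool)


class TestBhFdr:
    def test_single_rejection_example(self):
        res = hs.bh_fdr([0.001, 0.2, 0.9], q=0.05)
        assert res.rejected.tolist() == [True, False, False]
        assert res.p_threshold == pytest.approx(0.001)

    def test_all_ones_no_rejections(self):
        res = hs.bh_fdr(np.ones(10), q=0.05)
        assert not res.rejected.any() and res.p_threshold == 0.0

    def test_order_invariance(self):
        p = rng.uniform(size=30) ** 2
        perm = rng.permutation(30)
        a = hs.bh_fdr(p, 0.05).rejected
        b = hs.bh_fdr(p[perm], 0.05).rejected
        np.testing.assert_array_equal(a[perm], b)

    def test_monotone_in_q(self):
        p = rng.uniform(size=50) ** 3
        r1 = hs.bh_fdr(p, 0.01).rejected
        r2 = hs.bh_fdr(p, 0.05).rejected
        assert not (r1 & ~r2).any()

    def test_equals_brute_force_on_all_subsets(self):
        base = np.random.default_rng(7).uniform(size=10) ** 2
        for mask in range(1, 2**10):
            sub = base[[b == "1" for b in f"{mask:010b}"]]
            np.testing.assert_array_equal(
                hs.bh_fdr(sub, 0.05).rejected, brute_force_bh(sub, 0.05)
            )


class TestAnovaFamily:
    def test_two_groups_equals_pooled_t_squared(self):
        x, y = rng.normal(size=12), rng.normal(size=15) + 0.4
        f = hs.oneway_anova([x, y])
        t = sps.ttest_ind(x, y, equal_var=True)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert f.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        r = hs.oneway_anova([g, g, g])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_hand_sums_of_squares(self):
        groups = [[3.0, 5, 4, 6, 7], [8.0, 9, 7, 10, 11], [4.0, 6, 5, 5, 5]]
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(5 * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(((np.array(g) - np.mean(g)) ** 2).sum() for g in groups)
        expected_f = (ssb / 2) / (ssw / 12)
        assert hs.oneway_anova(groups).statistic == pytest.approx(expected_f, rel=1e-12)

    def test_rm_anova_matches_pingouin(self):
        n = 18
        groups = np.repeat(["A", "B", "C"], n)
        left = rng.normal(10, 2, 3 * n) + np.repeat([0, 0.5, 1.5], n)
        right = left + rng.normal(0.4, 1.2, 3 * n) + np.repeat([0, 0, 0.8], n)
        mine = hs.rm_anova_group_hemisphere(left, right, groups)
        df = pd.DataFrame(
            {
                "subject": np.tile(np.arange(3 * n), 2),
                "hemi": np.repeat(["L", "R"], 3 * n),
                "group": np.tile(groups, 2),
                "y": np.concatenate([left, right]),
            }
        )
        ref = pg.mixed_anova(df, dv="y", within="hemi", subject="subject", between="group")
        ref = ref.set_index("Source")
        assert mine["group"].statistic == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert mine["hemisphere"].statistic == pytest.approx(ref.loc["hemi", "F"], rel=1e-6)
        assert mine["interaction"].statistic == pytest.approx(ref.loc["Interaction", "F"], rel=1e-6)

    def test_rm_anova_single_group_reduces_to_paired_t(self):
        left = rng.normal(size=25)
        right = left + rng.normal(0.3, 0.5, 25)
        mine = hs.rm_anova_group_hemisphere(left, right, ["G"] * 25)
        t = sps.ttest_rel(right, left)
        assert mine["hemisphere"].statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert mine["hemisphere"].p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_constant_right_shift_moves_hemisphere_not_group(self):
        left = rng.normal(size=30)
        right = left + rng.normal(0, 0.5, 30)
        groups = np.repeat(["A", "B"], 15)
        base = hs.rm_anova_group_hemisphere(left, right, groups)
        shifted = hs.rm_anova_group_hemisphere(left, right + 5.0, groups)
        assert shifted["group"].statistic == pytest.approx(base["group"].statistic, rel=1e-9)
        assert shifted["hemisphere"].statistic > base["hemisphere"].statistic

    def test_missing_hemisphere_excluded_with_warning(self):
        left = np.array([1.0, 2, 3, np.nan, 5, 6])
        right = left + 1
        with pytest.warns(UserWarning, match="missing"):
            res = hs.rm_anova_group_hemisphere(left, right, ["A"] * 3 + ["B"] * 3)
        assert np.isfinite(res["group"].statistic)


class TestAncova:
    def test_orthogonal_covariate_leaves_f_unchanged(self):
        y = rng.normal(size=40) + np.repeat([0, 1.0], 20)
        groups = np.repeat(["A", "B"], 20)
        cov = np.concatenate([rng.normal(size=20), rng.normal(size=20)])
        cov[:20] -= cov[:20].mean()
        cov[20:] -= cov[20:].mean()  # orthogonal to the group contrast
        adj = hs.ancova(y, groups, cov[:, None])
        # oracle: pingouin ANCOVA on the same data
        df = pd.DataFrame({"y": y, "g": groups, "c": cov})
        ref = pg.ancova(data=df, dv="y", between="g", covar="c").set_index("Source")
        assert adj.statistic == pytest.approx(ref.loc["g", "F"], rel=1e-6)

    def test_perfect_covariate_kills_group_effect(self):
        y = rng.normal(size=30) + np.repeat([0, 2.0], 15)
        r = hs.ancova(y, np.repeat(["A", "B"], 15), y[:, None])
        assert r.statistic == pytest.approx(0.0, abs=1e-9)

    def test_matches_pingouin_on_unbalanced_three_groups(self):
        groups = np.array(["A"] * 10 + ["B"] * 14 + ["C"] * 12)
        cov = rng.normal(size=36)
        y = 0.7 * cov + rng.normal(size=36) + (groups == "C") * 0.8
        mine = hs.ancova(y, groups, cov[:, None])
        df = pd.DataFrame({"y": y, "g": groups, "c": cov})
        ref = pg.ancova(data=df, dv="y", between="g", covar="c").set_index("Source")
        assert mine.statistic == pytest.approx(ref.loc["g", "F"], rel=1e-6)
        assert mine.p_value == pytest.approx(ref.loc["g", "p_unc"], rel=1e-6)

    def test_rank_deficient_names_column(self):
        y = rng.normal(size=20)
        groups = np.repeat(["A", "B"], 10)
        cov = (groups == "B").astype(float)  # duplicates the group dummy
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            hs.ancova(y, groups, cov[:, None])


class TestWilksManova:
    def test_single_variable_reduces_to_anova(self):
        x = rng.normal(size=30) + np.repeat([0, 0.5, 1.0], 10)
        groups = np.repeat(["A", "B", "C"], 10)
        w = hs.wilks_manova(x[:, None], groups)
        f = hs.oneway_anova([x[:10], x[10:20], x[20:]])
        # Rao's F for p=1 is the one-way F with identical df
        lam_f = (1 - w.statistic) / w.statistic * w.df[1] / w.df[0]
        assert lam_f == pytest.approx(f.statistic, rel=1e-9)
        assert w.p_value == pytest.approx(f.p_value, rel=1e-9)

    def test_zero_between_scatter(self):
        block = rng.normal(size=(10, 3))
        scores = np.vstack([block, block])  # two groups with identical rows
        r = hs.wilks_manova(scores, np.repeat(["A", "B"], 10))
        assert r.statistic == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        scores = rng.normal(size=(45, 4))
        scores[15:30, 0] += 0.8
        scores[30:, 1] -= 0.6
        groups = np.repeat(["A", "B", "C"], 15)
        mine = hs.wilks_manova(scores, groups)
        df = pd.DataFrame(scores, columns=["v1", "v2", "v3", "v4"])
        df["g"] = groups
        mv = MANOVA.from_formula("v1 + v2 + v3 + v4 ~ g", data=df)
        tab = mv.mv_test().results["g"]["stat"]
        assert mine.statistic == pytest.approx(tab.loc["Wilks' lambda", "Value"], rel=1e-9)
        assert mine.p_value == pytest.approx(tab.loc["Wilks' lambda", "Pr > F"], rel=1e-6)

    def test_singular_within_instructs_truncation(self):
        scores = rng.normal(size=(6, 10))
        with pytest.raises(np.linalg.LinAlgError, match="truncation"):
            hs.wilks_manova(scores, ["A", "A", "A", "B", "B", "B"])


def _long_df(n_subj, weeks, sd=1.0, group_effects=None, seed=0):
    local = np.random.default_rng(seed)
    rows = []
    groups = group_effects or {"A": 0.0}
    for g, eff in groups.items():
        for s in range(n_subj):
            u = local.normal(0, 1.0)
            for w in weeks:
                rows.append(
                    {"subject": f"{g}{s}", "group": g, "week": w,
                     "volume": 10 + u + eff * w / 52 + local.normal(0, sd)}
                )
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_balanced_time_f_close_to_rm_anova(self):
        df = _long_df(24, [0, 12, 24, 52], seed=3)
        df.loc[df["week"] == 52, "volume"] += 0.8  # real time effect
        mine = hs.mixed_model_volume(df)
        ref = pg.rm_anova(data=df, dv="volume", within="week", subject="subject")
        f_ref = float(ref.loc[0, "F"])
        assert mine["time"].statistic == pytest.approx(f_ref, rel=0.05)

    def test_constant_volumes_time_p_one(self):
        rows = [
            {"subject": f"s{i}", "group": "A", "week": w, "volume": 5.0 + i}
            for i in range(6)
            for w in (0, 12, 24)
        ]
        r = hs.mixed_model_volume(pd.DataFrame(rows))
        assert r["time"].p_value == pytest.approx(1.0)

    def test_unbalanced_missing_visits_fit(self):
        df = _long_df(15, [0, 12, 24, 52], group_effects={"A": 0.0, "B": -2.0}, seed=4)
        df = df.sample(frac=0.7, random_state=1)  # drop 30% of visits
        res = hs.mixed_model_volume(df)
        assert set(res) == {"time", "group_x_time"}
        assert 0 <= res["group_x_time"].p_value <= 1

    def test_requires_repeat_visits(self):
        df = pd.DataFrame(
            {"subject": ["a", "b"], "group": ["A", "A"], "week": [0, 12], "volume": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="visits"):
            hs.mixed_model_volume(df)


class TestShapiro:
    def test_w_at_most_one_and_detects_exponential(self):
        rejections = 0
        for rep in range(200):
            local = np.random.default_rng(rep)
            r = hs.shapiro_normality(local.exponential(size=100))
            assert r.statistic <= 1.0
            rejections += r.p_value < 0.05
        assert rejections > 180  # > 90% power against exponential at n=100

    def test_constant_sample_degenerate(self):
        assert hs.shapiro_normality([2.0] * 10).p_value == 0.0


class TestPosthoc:
    def test_identical_samples_p_near_one(self):
        g = rng.normal(size=20)
        p = hs.pairwise_posthoc({"a": g, "b": g.copy()})
        assert p[("a", "b")] > 0.99

    def test_only_shifted_group_pairs_significant(self):
        base = {"a": rng.normal(size=25), "b": rng.normal(size=25),
                "c": rng.normal(size=25) + 3.0}
        p = hs.pairwise_posthoc(base)
        assert p[("a", "c")] < 0.001 and p[("b", "c")] < 0.001
        assert p[("a", "b")] > 0.05

    def test_pooled_t_oracle(self):
        groups = {"a": rng.normal(size=10), "b": rng.normal(size=12) + 1,
                  "c": rng.normal(size=9) - 0.5}
        p = hs.pairwise_posthoc(groups)
        n_tot = 31
        ms_w = sum(((g - g.mean()) ** 2).sum() for g in groups.values()) / (n_tot - 3)
        ga, gb = groups["a"], groups["b"]
        t = (ga.mean() - gb.mean()) / np.sqrt(ms_w * (1 / 10 + 1 / 12))
        expected = 2 * sps.t.sf(abs(t), n_tot - 3)
        assert p[("a", "b")] == pytest.approx(expected, rel=1e-9)

    def test_bonferroni_scales_p(self):
        groups = {"a": rng.normal(size=8), "b": rng.normal(size=8), "c": rng.normal(size=8)}
        raw = hs.pairwise_posthoc(groups)
        adj = hs.pairwise_posthoc(groups, correction="bonferroni")
        for pair in raw:
            assert adj[pair] == pytest.approx(min(1.0, raw[pair] * 3), rel=1e-12)
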