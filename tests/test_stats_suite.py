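"""Statistics suite: screens, contrasts, multivariate tests, cross-checks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from hrvtrial import (
    CohortSpec,
    DegenerateSampleError,
    InvalidInputError,
    between_effects_table,
    bonferroni_pairwise,
    estimated_marginal_means,
    gen_cohort,
    ks_normality,
    levene,
    mann_whitney,
    mixed_rm_anova,
    per_time_glm,
    roy_multivariate_tests,
)
from hrvtrial.core import _wide


def kolmogorov_series(t: float, terms: int = 200) -> float:
    """Textbook tail of the Kolmogorov distribution: 2 sum (-1)^{k-1} e^{-2k^2t^2}."""
    return 2.0 * sum(
        (-1) ** (k - 1) * math.exp(-2.0 * k * k * t * t) for k in range(1, terms + 1)
    )


class TestKSNormality:
    def test_near_perfect_fit_has_tiny_distance(self):
        n = 40
        probs = (np.arange(1, n + 1) - 0.5) / n
        x = sp_stats.norm.ppf(probs, loc=10.0, scale=2.0)
        d, p = ks_normality(x)
        assert d <= 1.0 / (2 * n) + 0.01
        assert p > 0.999

    def test_p_matches_kolmogorov_series_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.exponential(scale=2.0, size=20)
        d, p = ks_normality(x)
        assert p == pytest.approx(kolmogorov_series(math.sqrt(20) * d), abs=1e-6)

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            ks_normality([3.0, 3.0, 3.0, 3.0])

    def test_lilliefors_variant_is_more_conservative(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        _, p_legacy = ks_normality(x, method="legacy")
        _, p_lillie = ks_normality(x, method="lilliefors")
        assert p_lillie <= p_legacy + 1e-9

    def test_small_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            ks_normality([1.0, 2.0, 3.0])


class TestMannWhitney:
    def test_fully_separated_samples_exact_enumeration(self):
        """U = 0 and two-sided p = 2 * 1/C(6,3) = 0.1 by exhaustive
        enumeration of the 20 equally likely rank assignments."""
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_centre_u(self):
        u, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == 4.5
        assert p > 0.9

    def test_swap_symmetry(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(1.0, size=12)
        u_xy, p_xy = mann_whitney(x, y)
        u_yx, p_yx = mann_whitney(y, x)
        assert u_xy + u_yx == pytest.approx(8 * 12)
        assert p_xy == pytest.approx(p_yx, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_close_to_normal_approximation(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(0.5, size=10)
        _, p_exact = mann_whitney(x, y)
        res = sp_stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert abs(p_exact - res.pvalue) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            mann_whitney([], [1.0])


class TestLevene:
    def test_identical_groups_give_zero_F(self):
        f, p = levene([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_equals_anova_on_absolute_deviations(self, rng):
        g1 = rng.normal(0, 1, size=12)
        g2 = rng.normal(0, 3, size=9)
        f, p = levene([g1, g2])
        d1, d2 = np.abs(g1 - g1.mean()), np.abs(g2 - g2.mean())
        ref = sp_stats.f_oneway(d1, d2)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_scale_invariance_of_p(self, rng):
        g1 = rng.normal(size=10)
        g2 = rng.normal(0, 2, size=10)
        _, p1 = levene([g1, g2])
        _, p2 = levene([g1 * 7.3, g2 * 7.3])
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_undersized_group_rejected(self):
        with pytest.raises(InvalidInputError):
            levene([[1.0], [1.0, 2.0]])


class TestEMM:
    def test_zero_noise_margins_are_unweighted_cell_averages(self):
        df = gen_cohort(CohortSpec(error_sd=0.0, seed=0))
        emm = estimated_marginal_means(df)
        # T1: control 56.800, experimental 55.725 -> margin 56.2625
        assert emm["time_margins"]["T1"] == pytest.approx(56.2625, abs=1e-9)
        assert emm["cell_means"].loc["control", "T4"] == pytest.approx(64.970)

    def test_equal_group_sizes_weighted_equals_unweighted(self):
        df = gen_cohort(CohortSpec(n_control=10, n_experimental=10, seed=8))
        u = estimated_marginal_means(df, "unweighted")["time_margins"]
        w = estimated_marginal_means(df, "weighted")["time_margins"]
        assert np.allclose(u.to_numpy(float), w.to_numpy(float))

    def test_shift_equivariance(self, default_cohort):
        shifted = default_cohort.copy()
        shifted["pei_percent"] += 5.0
        e0 = estimated_marginal_means(default_cohort)
        e1 = estimated_marginal_means(shifted)
        assert np.allclose(
            e1["cell_means"].to_numpy(), e0["cell_means"].to_numpy() + 5.0
        )

    def test_missing_cell_rejected(self, default_cohort):
        broken = default_cohort[default_cohort["group"] == "control"]
        with pytest.raises(InvalidInputError):
            estimated_marginal_means(broken)


class TestBonferroni:
    @pytest.mark.parametrize(
        "diff, se, p3, lo, hi",
        [
            (-3.195, 0.908, 0.009, -5.773, -0.617),
            (-5.613, 1.505, 0.005, -9.884, -1.341),
        ],
    )
    def test_published_contrast_arithmetic(self, diff, se, p3, lo, hi):
        c = bonferroni_pairwise(diff, se, df=28, k=6)
        assert round(c.p_adj, 3) == p3
        assert c.ci_low == pytest.approx(lo, abs=2.5e-3)
        assert c.ci_high == pytest.approx(hi, abs=2.5e-3)

    def test_null_difference_capped_at_one(self):
        c = bonferroni_pairwise(0.0, 1.0, df=28, k=6)
        assert c.p_adj == 1.0
        assert c.ci_low == pytest.approx(-c.ci_high)

    def test_antisymmetry(self):
        a = bonferroni_pairwise(2.5, 0.7, df=20, k=6)
        b = bonferroni_pairwise(-2.5, 0.7, df=20, k=6)
        assert a.p_adj == b.p_adj
        assert a.ci_low == pytest.approx(-b.ci_high)
        assert a.ci_high == pytest.approx(-b.ci_low)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(InvalidInputError):
            bonferroni_pairwise(1.0, 0.0, df=28, k=6)


class TestBetweenEffects:
    def test_published_between_table(self):
        rows = between_effects_table(
            {"Intercept": (385970.522, 1), "Group": (129.360, 1)}, 662.548, 28
        )
        by_name = {r.source: r for r in rows}
        assert by_name["Group"].F == pytest.approx(5.467, abs=5e-4)
        assert by_name["Group"].p == pytest.approx(0.027, abs=5e-4)
        assert by_name["Group"].partial_eta_sq == pytest.approx(0.163, abs=1e-3)
        assert by_name["Intercept"].partial_eta_sq == pytest.approx(0.998, abs=1e-3)
        assert by_name["Error"].ms == pytest.approx(23.662, abs=5e-4)

    def test_zero_effect(self):
        rows = between_effects_table({"Group": (0.0, 1)}, 10.0, 5)
        assert rows[0].F == 0.0 and rows[0].partial_eta_sq == 0.0

    def test_zero_error_ss_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            between_effects_table({"Group": (1.0, 1)}, 0.0, 5)


class TestPerTimeGLM:
    def test_matches_statsmodels_ols(self, default_cohort):
        import statsmodels.api as sm

        for tp in ("T1", "T3"):
            row = per_time_glm(default_cohort, tp)
            sub = default_cohort[default_cohort["timepoint"] == tp]
            g = (sub["group"] == "experimental").astype(float).to_numpy()
            X = sm.add_constant(g)
            fit = sm.OLS(sub["pei_percent"].to_numpy(), X).fit()
            assert row.intercept == pytest.approx(fit.params[0], rel=1e-10)
            assert row.B == pytest.approx(fit.params[1], rel=1e-10)
            assert row.se_B == pytest.approx(fit.bse[1], rel=1e-10)
            assert row.p == pytest.approx(fit.pvalues[1], rel=1e-10)
            assert row.eta_sq == pytest.approx(
                row.t**2 / (row.t**2 + row.df), rel=1e-12
            )

    def test_identical_group_means_give_null_effect(self):
        rows = []
        for g, n in (("control", 4), ("experimental", 4)):
            for i in range(n):
                for tp in ("T1", "T2", "T3", "T4"):
                    rows.append((f"{g[0]}{i}", g, tp, 50.0 + i))
        df = pd.DataFrame(rows, columns=["subject_id", "group", "timepoint", "pei_percent"])
        row = per_time_glm(df, "T1")
        assert row.B == pytest.approx(0.0, abs=1e-12)
        assert row.eta_sq == pytest.approx(0.0, abs=1e-12)
        assert row.p == pytest.approx(1.0, abs=1e-9)

    def test_missing_group_rejected(self, default_cohort):
        only_ctrl = default_cohort[default_cohort["group"] == "control"]
        with pytest.raises(InvalidInputError):
            per_time_glm(only_ctrl, "T1")


class TestMixedRMAnova:
    def test_H_and_E_match_bruteforce_group_mean_algebra(self, default_cohort):
        """Roy's root recomputed from closed-form H and E built out of the
        group mean vectors and pooled within-group cross-products."""
        Y, is_exp, _ = _wide(default_cohort)
        D = Y[:, 1:] - Y[:, :-1]
        d1, d2 = D[~is_exp], D[is_exp]
        n1, n2 = len(d1), len(d2)
        N = n1 + n2
        m1, m2 = d1.mean(axis=0), d2.mean(axis=0)
        E = sum((r - m1)[:, None] @ (r - m1)[None, :] for r in d1) + sum(
            (r - m2)[:, None] @ (r - m2)[None, :] for r in d2
        )
        H_time = (n1 * n2 / N) * np.outer(m1 + m2, m1 + m2)
        H_inter = (n1 * n2 / N) * np.outer(m1 - m2, m1 - m2)
        report = mixed_rm_anova(default_cohort)
        for test, H in zip(report.roy_tests, (H_time, H_inter)):
            lam = np.max(np.real(np.linalg.eigvals(np.linalg.solve(E, H))))
            assert test.largest_root == pytest.approx(lam, abs=1e-10)

    def test_roy_matches_statsmodels_manova(self, default_cohort):
        from statsmodels.multivariate.manova import MANOVA

        Y, is_exp, _ = _wide(default_cohort)
        D = Y[:, 1:] - Y[:, :-1]
        X = np.column_stack([np.ones(len(D)), np.where(is_exp, -1.0, 1.0)])
        res = MANOVA(endog=D, exog=X).mv_test(
            hypotheses=[
                ("TIME", np.array([[1.0, 0.0]]), None),
                ("INTER", np.array([[0.0, 1.0]]), None),
            ]
        )
        report = mixed_rm_anova(default_cohort)
        for name, mine in zip(("TIME", "INTER"), report.roy_tests):
            row = res.results[name]["stat"].loc["Roy's greatest root"]
            assert mine.largest_root == pytest.approx(float(row["Value"]), rel=1e-9)
            assert mine.F == pytest.approx(float(row["F Value"]), rel=1e-9)
            assert mine.p == pytest.approx(float(row["Pr > F"]), rel=1e-9, abs=1e-12)

    def test_single_contrast_roy_equals_univariate_F(self, default_cohort):
        """With one difference variable, Roy's exact F is the univariate F."""
        Y, is_exp, _ = _wide(default_cohort)
        d = (Y[:, 1] - Y[:, 0])[:, None]
        tests = roy_multivariate_tests(d, is_exp)
        d1, d2 = d[~is_exp, 0], d[is_exp, 0]
        n1, n2, N = d1.size, d2.size, d.size
        s2 = ((n1 - 1) * d1.var(ddof=1) + (n2 - 1) * d2.var(ddof=1)) / (N - 2)
        # univariate F for the unweighted mean (TIME) and group difference
        t_time = 0.5 * (d1.mean() + d2.mean()) / math.sqrt(
            0.25 * s2 * (1 / n1 + 1 / n2)
        )
        t_inter = (d1.mean() - d2.mean()) / math.sqrt(s2 * (1 / n1 + 1 / n2))
        for test, t_stat in zip(tests, (t_time, t_inter)):
            F_uni = t_stat**2
            p_uni = float(sp_stats.f.sf(F_uni, 1, N - 2))
            assert test.F == pytest.approx(F_uni, abs=1e-10)
            assert test.p == pytest.approx(p_uni, abs=1e-10)

    def test_pairwise_self_consistency(self, default_cohort):
        report = mixed_rm_anova(default_cohort)
        for c in report.pairwise:
            redo = bonferroni_pairwise(c.diff, c.se, c.df, c.k, pair=c.pair)
            assert redo.p_adj == pytest.approx(c.p_adj, abs=1e-12)
            assert redo.ci_low == pytest.approx(c.ci_low, abs=1e-12)

    def test_pairwise_ses_in_reported_range(self, default_cohort):
        ses = [c.se for c in mixed_rm_anova(default_cohort).pairwise]
        assert all(0.5 < se < 2.0 for se in ses)

    def test_constant_data_flagged_degenerate(self):
        rows = [
            (f"{g[0]}{i}", g, tp, 60.0)
            for g, n in (("control", 3), ("experimental", 3))
            for i in range(n)
            for tp in ("T1", "T2", "T3", "T4")
        ]
        df = pd.DataFrame(rows, columns=["subject_id", "group", "timepoint", "pei_percent"])
        report = mixed_rm_anova(df)
        assert report.degenerate
        assert report.roy_tests == [] and report.pairwise == []

    def test_incomplete_data_rejected_not_dropped(self, default_cohort):
        with pytest.raises(InvalidInputError):
            mixed_rm_anova(default_cohort.iloc[:-2])
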