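"""Group-statistics layer: t tests from summaries and samples, nonparametric
tests, repeated-measures ANOVA against a brute-force oracle, BH-FDR against
the hand step-up rule, and gait comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import nirsgait as ng
from nirsgait.core import ValidationError
from nirsgait.stats import (
    SummaryStats,
    bh_fdr,
    gait_compare,
    kruskal_wallis,
    mann_whitney,
    normality_gate,
    paired_t,
    rm_anova,
    ttest_from_samples,
    ttest_from_summary,
    two_group_test,
)


class TestTTest:
    def test_published_row_reproduced_from_summaries(self):
        """S1-PFC connectivity cells: HC 0.124 +- 0.112 vs PD 0.239 +- 0.171,
        n = 28/28 -> t ~ -2.97, pooled-SD d ~ 0.80."""
        res = ttest_from_summary(SummaryStats(0.124, 0.112, 28), SummaryStats(0.239, 0.171, 28))
        assert res.statistic == pytest.approx(-2.977, abs=0.01)
        assert res.effect == pytest.approx(0.796, abs=0.005)
        assert res.df == 54
        assert res.p < 0.01

    def test_identical_summaries_give_zero(self):
        res = ttest_from_summary(SummaryStats(1.0, 0.5, 10), SummaryStats(1.0, 0.5, 10))
        assert res.statistic == 0.0
        assert res.effect == 0.0
        assert res.p == pytest.approx(1.0)

    def test_hand_example(self):
        # (mean 0, sd 1, n 2) vs (mean 1, sd 1, n 2): t = -1.0
        res = ttest_from_summary(SummaryStats(0.0, 1.0, 2), SummaryStats(1.0, 1.0, 2))
        assert res.statistic == pytest.approx(-1.0)

    def test_samples_agree_with_summary_to_1e12(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 28), rng.normal(0.5, 1.2, 28)
        a = ttest_from_samples(x, y)
        b = ttest_from_summary(SummaryStats.of(x), SummaryStats.of(y))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 20), rng.normal(0.3, 1, 25)
        res = ttest_from_samples(x, y)
        ref = sps.ttest_ind(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
        welch = ttest_from_samples(x, y, welch=True)
        ref_w = sps.ttest_ind(x, y, equal_var=False)
        assert welch.statistic == pytest.approx(ref_w.statistic, abs=1e-10)
        assert welch.p == pytest.approx(ref_w.pvalue, abs=1e-10)

    def test_equal_n_pooled_identity(self):
        """For n_a = n_b = n: t = (m1 - m2) / sqrt((s1^2 + s2^2) / n)."""
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=28), rng.normal(0.4, 1.3, size=28)
        a, b = SummaryStats.of(x), SummaryStats.of(y)
        res = ttest_from_summary(a, b)
        assert res.statistic == pytest.approx(
            (a.mean - b.mean) / np.sqrt((a.sd**2 + b.sd**2) / 28), abs=1e-12
        )

    def test_zero_variance_degenerate_cases(self):
        eq = ttest_from_summary(SummaryStats(1.0, 0.0, 5), SummaryStats(1.0, 0.0, 5))
        assert eq.statistic == 0.0 and eq.p == 1.0
        ne = ttest_from_summary(SummaryStats(1.0, 0.0, 5), SummaryStats(2.0, 0.0, 5))
        assert np.isinf(ne.statistic) and ne.p == 0.0

    def test_type_i_error_calibrated(self):
        """Null t-test rejects at 0.05 +- 0.01 over 2000 replicates (n=28/28)."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2000, 28))
        y = rng.standard_normal((2000, 28))
        # vectorized pooled t
        mx, my = x.mean(1), y.mean(1)
        vx, vy = x.var(1, ddof=1), y.var(1, ddof=1)
        t = (mx - my) / np.sqrt((vx + vy) / 28)
        p = 2 * sps.t.sf(np.abs(t), 54)
        rate = (p < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.01)


class TestNonparametric:
    def test_u_of_separated_groups_is_zero(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert min(res.statistic, 9 - res.statistic) == 0.0

    def test_identical_groups_p_near_one(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p > 0.9

    def test_all_tied_warns_p_one(self):
        res = mann_whitney([2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0
        assert "tied" in res.warnings[0]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_u_identity(self, seed):
        """U(x, y) + U(y, x) = n_x * n_y."""
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=8), rng.normal(size=13)
        u_xy = mann_whitney(x, y).statistic
        u_yx = mann_whitney(y, x).statistic
        assert u_xy + u_yx == pytest.approx(8 * 13)

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=15), rng.normal(0.8, 1, size=12)
        res = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.statistic == ref.statistic
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_kruskal_matches_scipy(self):
        rng = np.random.default_rng(6)
        g = [rng.normal(size=10), rng.normal(0.5, 1, 12), rng.normal(1.0, 1, 9)]
        res = kruskal_wallis(g)
        ref = sps.kruskal(*g)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.df == 2


class TestNormalityGate:
    def test_normal_samples_route_parametric(self):
        rng = np.random.default_rng(7)
        hits = [normality_gate([rng.normal(size=50), rng.normal(size=50)])[0] == "parametric"
                for _ in range(50)]
        assert np.mean(hits) >= 0.9

    def test_lognormal_routes_nonparametric(self):
        rng = np.random.default_rng(8)
        hits = [normality_gate([np.exp(rng.normal(0, 1, 50))])[0] == "nonparametric"
                for _ in range(50)]
        assert np.mean(hits) >= 0.9

    def test_constant_sample_nonparametric_with_warning(self):
        route, ps, notes = normality_gate([np.full(10, 2.0)])
        assert route == "nonparametric"
        assert any("zero variance" in n for n in notes)

    def test_tiny_sample_nonparametric_with_warning(self):
        route, _, notes = normality_gate([np.array([1.0, 2.0])])
        assert route == "nonparametric"
        assert notes


def brute_force_rm_anova(data: np.ndarray) -> tuple[float, float]:
    """Sums-of-squares decomposition by explicit loops (independent oracle)."""
    n, k = data.shape
    grand = data.mean()
    ss_cond = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((data[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    f = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    eta2 = ss_cond / (ss_cond + ss_err)
    return f, eta2


class TestRMAnova:
    def test_identical_conditions_give_zero(self):
        data = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        res = rm_anova(data)
        assert res.statistic == 0.0
        assert res.effect == 0.0

    def test_toy_design_matches_brute_force_and_f_equals_t_squared(self):
        data = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        # perfectly consistent within-subject shift: error SS is 0 -> infinite F
        res = rm_anova(data)
        assert np.isinf(res.statistic)
        noisy = data + np.array([[0.0, 0.1], [0.0, -0.2], [0.0, 0.05]])
        res = rm_anova(noisy)
        f_ref, eta_ref = brute_force_rm_anova(noisy)
        assert res.statistic == pytest.approx(f_ref, abs=1e-9)
        assert res.effect == pytest.approx(eta_ref, abs=1e-9)
        t = paired_t(noisy[:, 0], noisy[:, 1]).statistic
        assert res.statistic == pytest.approx(t**2, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_random_designs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(3, 9)), int(rng.integers(2, 5))
        data = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
        res = rm_anova(data)
        f_ref, eta_ref = brute_force_rm_anova(data)
        assert res.statistic == pytest.approx(f_ref, rel=1e-9)
        assert res.effect == pytest.approx(eta_ref, rel=1e-9)
        assert 0.0 <= res.effect <= 1.0
        assert res.df == (k - 1, (k - 1) * (n - 1))

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        n, k = 12, 4
        data = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
        res = rm_anova(data)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "cond": np.tile(np.arange(k), n),
                "y": data.reshape(-1),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subject", detailed=True)
        assert res.statistic == pytest.approx(ref.loc[0, "F"], rel=1e-6)
        assert res.p == pytest.approx(ref.loc[0, "p_unc"], rel=1e-6)
        ss_cond, ss_err = ref.loc[0, "SS"], ref.loc[1, "SS"]
        assert res.effect == pytest.approx(ss_cond / (ss_cond + ss_err), rel=1e-6)

    def test_incomplete_design_rejected(self):
        data = np.random.default_rng(11).normal(size=(5, 3))
        data[2, 1] = np.nan
        with pytest.raises(ValidationError, match="missing cells"):
            rm_anova(data)

    def test_lsd_posthoc_is_uncorrected_paired_t(self):
        rng = np.random.default_rng(12)
        data = rng.normal(size=(8, 3))
        res = rm_anova(data, condition_labels=["NONE", "RAS_B", "RAS_M"])
        ph = res.posthoc[("NONE", "RAS_B")]
        ref = sps.ttest_rel(data[:, 0], data[:, 1])
        assert ph.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ph.p == pytest.approx(ref.pvalue, abs=1e-10)
        assert len(res.posthoc) == 3


class TestBHFDR:
    def test_single_p_unchanged(self):
        adj, rej = bh_fdr([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_hand_step_up_example(self):
        adj, _ = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_empty_input(self):
        adj, rej = bh_fdr([])
        assert adj.size == 0 and rej.size == 0

    def _hand_step_up(self, p):
        """Literal step-up definition: adj_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        for rank_pos, idx in enumerate(order):
            candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
            adj[idx] = min(1.0, min(candidates))
        return adj

    def test_matches_hand_oracle_on_small_grids(self):
        grid = [0.0, 0.005, 0.01, 0.04, 0.05, 0.2, 0.5, 1.0]
        for m in (1, 2, 3):
            for combo in itertools.product(grid, repeat=m):
                adj, _ = bh_fdr(list(combo))
                np.testing.assert_allclose(adj, self._hand_step_up(combo), atol=1e-12)
        rng = np.random.default_rng(13)
        for m in (4, 5):
            for _ in range(300):
                p = rng.uniform(size=m)
                adj, _ = bh_fdr(p)
                np.testing.assert_allclose(adj, self._hand_step_up(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(14)
        p = rng.uniform(size=48)
        adj, rej = bh_fdr(p)
        ref_rej, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adj, ref_adj, atol=1e-12)
        np.testing.assert_array_equal(rej, ref_rej)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_and_dominates_raw(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(1, 40)))
        adj, _ = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_rejections_superset_of_bonferroni(self):
        """BH at q rejects everything Bonferroni at alpha = q rejects."""
        rng = np.random.default_rng(15)
        for _ in range(1000):
            m = int(rng.integers(1, 30))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            _, bh_rej = bh_fdr(p, q=0.05)
            bonf_rej = p <= 0.05 / m
            assert np.all(bh_rej[bonf_rej])


class TestGaitCompare:
    def _records(self, seed=0, velocity_deficit=0.36, n=28):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n):
            z = rng.standard_normal()
            base = dict(cadence=100 + 8 * z, stride_length=max(0.1, 0.9 + 0.1 * z),
                        swing_width=max(1.0, 10 + 2 * z), foot_progression_angle=max(0.1, 6 + 2 * z))
            for cond, interv in [("freeze_induction", "NONE"), ("normal_walk", "NONE"),
                                 ("freeze_induction", "RAS_B"), ("freeze_induction", "RAS_M"),
                                 ("freeze_induction", "RAS_I")]:
                v = 0.8 + 0.12 * z + 0.08 * rng.standard_normal()
                if cond == "freeze_induction":
                    v -= velocity_deficit if interv == "NONE" else velocity_deficit * 0.6
                fog = int(rng.poisson(3)) if cond == "freeze_induction" else 0
                rows.append(dict(subject_id=f"P{s}", group="PD_FOG", condition=cond,
                                 intervention=interv, velocity=max(0.05, v), fog_count=fog, **base))
        return pd.DataFrame(rows)

    def test_identical_paired_values_give_zero_statistic(self):
        df = self._records(velocity_deficit=0.0, seed=1)
        # force exact equality between conditions
        wide = df[df.intervention == "NONE"].copy()
        v = wide[wide.condition == "freeze_induction"]["velocity"].to_numpy()
        df.loc[(df.intervention == "NONE") & (df.condition == "normal_walk"), "velocity"] = v
        out = gait_compare(df, "freeze_vs_normal")
        row = out[out["label"] == "velocity"].iloc[0]
        assert row["statistic"] == 0.0

    def test_velocity_deficit_detected_with_power(self):
        """Paired deficit of about one within-subject SD rejects in >= 80% of seeds."""
        rejections = []
        for seed in range(100):
            df = self._records(seed=seed, velocity_deficit=0.115)  # ~1 sd_diff
            out = gait_compare(df, "freeze_vs_normal")
            rejections.append(out[out["label"] == "velocity"].iloc[0]["p"] < 0.05)
        assert np.mean(rejections) >= 0.8

    def test_fog_counts_routed_nonparametric(self):
        hits = []
        for seed in range(30):
            df = self._records(seed=seed)
            out = gait_compare(df, "freeze_vs_normal")
            hits.append(out[out["label"] == "fog_count"].iloc[0]["test_name"] in ("wilcoxon",))
        assert np.mean(hits) >= 0.9

    def test_interventions_contrast_shapes(self):
        df = self._records(seed=3)
        out = gait_compare(df, "interventions")
        assert set(out["label"]) == {"cadence", "stride_length", "velocity",
                                     "swing_width", "foot_progression_angle", "fog_count"}
        assert set(out["test_name"]) <= {"rm_anova", "friedman"}

    def test_unmatched_subjects_rejected(self):
        df = self._records(seed=4)
        df = df[~((df.subject_id == "P0") & (df.condition == "normal_walk"))]
        df = df[df.subject_id.isin([f"P{i}" for i in range(2)])]
        with pytest.raises(ValidationError):
            gait_compare(df, "freeze_vs_normal")


class TestTwoGroupGate:
    def test_routes_by_normality(self):
        rng = np.random.default_rng(16)
        res = two_group_test(rng.normal(size=40), rng.normal(0.3, 1, 40))
        assert res.test_name == "student_t"
        res = two_group_test(np.exp(rng.normal(0, 1.5, 40)), np.exp(rng.normal(0.3, 1.5, 40)))
        assert res.test_name == "mann_whitney_u"
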