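"""Group-statistics layer: normality gating, two-sample and nonparametric
tests, summary-statistic t and Cohen's d, one-way repeated-measures ANOVA with
partial eta squared and LSD post-hoc, Benjamini-Hochberg FDR, and gait
comparisons.

Conventions: Student (pooled-variance) t is the default two-group test
(Welch available via flag); Cohen's d uses the pooled SD, signed as
(mean_b - mean_a) / s_p so that a patient-minus-control contrast reported
with a negative t carries a positive d, matching published tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GAIT_PARAMETERS, INTERVENTIONS, ValidationError

__all__ = [
    "SummaryStats",
    "StatResult",
    "normality_gate",
    "ttest_from_summary",
    "ttest_from_samples",
    "mann_whitney",
    "kruskal_wallis",
    "rm_anova",
    "paired_t",
    "bh_fdr",
    "gait_compare",
    "two_group_test",
]


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.n < 2:
            raise ValidationError("n must be >= 2")

    @classmethod
    def of(cls, x) -> "SummaryStats":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=len(x))


@dataclass
class StatResult:
    test_name: str
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    effect: float | None = None
    effect_kind: str = ""
    p_adjusted: float | None = None
    warnings: tuple[str, ...] = ()
    posthoc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 or np.isnan(self.p)):
            raise ValidationError(f"p = {self.p} outside [0, 1]")
        if self.p_adjusted is not None and not np.isnan(self.p_adjusted):
            if not 0 <= self.p_adjusted <= 1:
                raise ValidationError("p_adjusted outside [0, 1]")
            if self.p_adjusted < self.p - 1e-12:
                raise ValidationError("p_adjusted must be >= p")


# ---------------------------------------------------------------------------
# Normality gating
# ---------------------------------------------------------------------------


def normality_gate(groups: list[np.ndarray], alpha: float = 0.05) -> tuple[str, list[float], list[str]]:
    """Route to 'parametric' or 'nonparametric' via per-group Shapiro-Wilk.

    Parametric iff every group passes (p > alpha). Groups with n < 3 or zero
    variance cannot be tested and force the nonparametric route with a
    warning. Returns (route, shapiro p per group, warnings).
    """
    ps: list[float] = []
    notes: list[str] = []
    route = "parametric"
    for k, g in enumerate(groups):
        g = np.asarray(g, dtype=float)
        if len(g) < 3:
            notes.append(f"group {k}: n < 3, normality untestable")
            route = "nonparametric"
            ps.append(np.nan)
        elif np.ptp(g) == 0:
            notes.append(f"group {k}: zero variance")
            route = "nonparametric"
            ps.append(np.nan)
        else:
            p = float(sps.shapiro(g).pvalue)
            ps.append(p)
            if p <= alpha:
                route = "nonparametric"
    return route, ps, notes


# ---------------------------------------------------------------------------
# Two-sample tests
# ---------------------------------------------------------------------------


def ttest_from_summary(a: SummaryStats, b: SummaryStats, welch: bool = False) -> StatResult:
    """Independent two-sample t from group summaries.

    Student (pooled) form: t = (m_a - m_b) / sqrt(s_p^2 (1/n_a + 1/n_b)),
    df = n_a + n_b - 2; Cohen's d = (m_b - m_a) / s_p with the pooled SD.
    """
    diff = a.mean - b.mean
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    notes: tuple[str, ...] = ()
    if welch:
        se2 = a.sd**2 / a.n + b.sd**2 / b.n
        if se2 == 0:
            return _degenerate_t(diff, a, b, "welch_t")
        t = diff / np.sqrt(se2)
        df = se2**2 / ((a.sd**2 / a.n) ** 2 / (a.n - 1) + (b.sd**2 / b.n) ** 2 / (b.n - 1))
        name = "welch_t"
    else:
        if sp2 == 0:
            return _degenerate_t(diff, a, b, "student_t")
        t = diff / np.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df = a.n + b.n - 2
        name = "student_t"
    p = 2 * sps.t.sf(abs(t), df)
    d = (b.mean - a.mean) / np.sqrt(sp2) if sp2 > 0 else 0.0
    return StatResult(name, float(t), float(df), float(p), float(d), "cohen_d", warnings=notes)


def _degenerate_t(diff: float, a: SummaryStats, b: SummaryStats, name: str) -> StatResult:
    if diff == 0:
        return StatResult(name, 0.0, a.n + b.n - 2, 1.0, 0.0, "cohen_d",
                          warnings=("zero variance in both groups",))
    return StatResult(name, np.inf if diff > 0 else -np.inf, a.n + b.n - 2, 0.0, np.nan, "cohen_d",
                      warnings=("zero variance with unequal means: infinite t",))


def ttest_from_samples(x, y, welch: bool = False) -> StatResult:
    """Independent t-test on raw samples (identical to the summary form)."""
    return ttest_from_summary(SummaryStats.of(x), SummaryStats.of(y), welch=welch)


def mann_whitney(x, y) -> StatResult:
    """Mann-Whitney U with normal approximation (tie corrected).

    Effect size is the rank-biserial correlation 1 - 2U/(n_x n_y).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs n >= 2")
    if np.ptp(np.concatenate([x, y])) == 0:
        return StatResult("mann_whitney_u", len(x) * len(y) / 2, None, 1.0, 0.0, "rank_biserial",
                          warnings=("all values tied",))
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    rb = 1.0 - 2.0 * res.statistic / (len(x) * len(y))
    return StatResult("mann_whitney_u", float(res.statistic), None, float(res.pvalue), float(rb), "rank_biserial")


def kruskal_wallis(groups: list) -> StatResult:
    """Kruskal-Wallis H across >= 2 groups (chi-square approximation)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 groups with n >= 2 each")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if np.ptp(pooled) == 0:
        return StatResult("kruskal_wallis_h", 0.0, len(groups) - 1, 1.0, 0.0, "eta_squared_h",
                          warnings=("all values tied",))
    res = sps.kruskal(*groups)
    n, k = len(pooled), len(groups)
    eta2 = max(0.0, (res.statistic - k + 1) / (n - k))
    return StatResult("kruskal_wallis_h", float(res.statistic), k - 1, float(res.pvalue), float(eta2), "eta_squared_h")


def paired_t(x, y) -> StatResult:
    """Paired t-test; effect is Cohen's d_z (mean difference / SD of differences)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError("paired samples must have equal length")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        p = 1.0 if d.mean() == 0 else 0.0
        stat = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
        return StatResult("paired_t", float(stat), len(d) - 1, p, 0.0, "cohen_dz",
                          warnings=("zero-variance differences",))
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2 * sps.t.sf(abs(t), len(d) - 1)
    return StatResult("paired_t", float(t), len(d) - 1, float(p), float(d.mean() / sd), "cohen_dz")


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------


def rm_anova(data: np.ndarray, condition_labels: list[str] | None = None, lsd: bool = True) -> StatResult:
    """One-way repeated-measures ANOVA with subject as blocking factor.

    ``data`` is (n_subjects, k_conditions), complete cases only.
    F = MS_condition / MS_error with df (k-1, (k-1)(n-1));
    partial eta^2 = SS_cond / (SS_cond + SS_error). LSD post-hoc: uncorrected
    pairwise paired t-tests over all condition pairs.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValidationError("design must be a 2-D subjects x conditions array")
    n, k = data.shape
    if k < 2 or n < 3:
        raise ValidationError("need >= 2 conditions and >= 3 subjects")
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))
        cells = [f"(subject {i}, condition {j})" for i, j in bad[:5]]
        raise ValidationError(f"incomplete design; missing cells: {', '.join(cells)}")
    labels = condition_labels or [f"c{j}" for j in range(k)]
    grand = data.mean()
    ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    ms_cond, ms_err = ss_cond / df_cond, ss_err / df_err
    if ms_err <= 0:
        f, p = (0.0, 1.0) if ss_cond == 0 else (np.inf, 0.0)
    else:
        f = ms_cond / ms_err
        p = float(sps.f.sf(f, df_cond, df_err))
    eta2 = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    posthoc = {}
    if lsd:
        for i, j in combinations(range(k), 2):
            posthoc[(labels[i], labels[j])] = paired_t(data[:, i], data[:, j])
    return StatResult(
        "rm_anova", float(f), (df_cond, df_err), float(p), float(eta2), "partial_eta_squared", posthoc=posthoc
    )


# ---------------------------------------------------------------------------
# Multiple comparisons
# ---------------------------------------------------------------------------


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and the rejection set at ``q``.

    Adjusted p for the i-th smallest p is min_{j >= i} (m p_(j) / j), capped
    at 1, which enforces monotonicity and elementwise p_adj >= p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, adj <= q


# ---------------------------------------------------------------------------
# Composite comparisons
# ---------------------------------------------------------------------------


def two_group_test(x, y, alpha: float = 0.05) -> StatResult:
    """Normality-gated two-group comparison: Student t or Mann-Whitney U."""
    route, _, notes = normality_gate([np.asarray(x, float), np.asarray(y, float)], alpha=alpha)
    res = ttest_from_samples(x, y) if route == "parametric" else mann_whitney(x, y)
    if notes:
        res.warnings = tuple(res.warnings) + tuple(notes)
    return res


def _pivot_paired(df: pd.DataFrame, value: str, index: str, columns: str, order: list[str]) -> pd.DataFrame:
    wide = df.pivot_table(index=index, columns=columns, values=value)
    missing = [c for c in order if c not in wide.columns]
    if missing:
        raise ValidationError(f"missing {columns} levels: {missing}")
    wide = wide[order].dropna()
    return wide


def gait_compare(records: pd.DataFrame, contrast: str, alpha: float = 0.05) -> pd.DataFrame:
    """Gait-parameter statistics on a long gait table.

    ``contrast='freeze_vs_normal'``: paired tests (no-intervention
    freeze-induction vs normal walking) per parameter, normality-gated
    between paired t and Wilcoxon signed-rank. ``contrast='interventions'``:
    one-way repeated-measures ANOVA (Friedman when the gate fails) across the
    four intervention conditions during freeze-induction walking. Freezing
    counts are integer and skewed, so the gate routes them nonparametrically.
    Subjects must be matched across contrast levels.
    """
    params = list(GAIT_PARAMETERS) + ["fog_count"]
    rows = []
    if contrast == "freeze_vs_normal":
        sub = records[(records["intervention"] == "NONE")]
        for p in params:
            wide = _pivot_paired(sub, p, "subject_id", "condition", ["freeze_induction", "normal_walk"])
            if len(wide) < 3:
                raise ValidationError("fewer than 3 matched subjects for the paired contrast")
            x, y = wide["freeze_induction"].to_numpy(), wide["normal_walk"].to_numpy()
            route, _, notes = normality_gate([x, y], alpha=alpha)
            if route == "parametric":
                res = paired_t(x, y)
            else:
                diffs = x - y
                if np.all(diffs == 0):
                    res = StatResult("wilcoxon", 0.0, None, 1.0, 0.0, "rank_biserial",
                                     warnings=("all paired differences zero",))
                else:
                    w = sps.wilcoxon(x, y, zero_method="wilcox")
                    nz = np.count_nonzero(diffs)
                    rb = 1.0 - 4.0 * w.statistic / (nz * (nz + 1))
                    res = StatResult("wilcoxon", float(w.statistic), None, float(w.pvalue), float(rb), "rank_biserial")
            res.warnings = tuple(res.warnings) + tuple(notes)
            rows.append(_result_row(p, res))
    elif contrast == "interventions":
        sub = records[records["condition"] == "freeze_induction"]
        order = list(INTERVENTIONS)
        for p in params:
            wide = _pivot_paired(sub, p, "subject_id", "intervention", order)
            if len(wide) < 3:
                raise ValidationError("fewer than 3 matched subjects for the repeated-measures contrast")
            cols = [wide[c].to_numpy() for c in order]
            route, _, notes = normality_gate(cols, alpha=alpha)
            if route == "parametric":
                res = rm_anova(wide.to_numpy(), condition_labels=order)
            else:
                fr = sps.friedmanchisquare(*cols)
                # Kendall's W from the Friedman chi-square
                n, k = wide.shape
                res = StatResult("friedman", float(fr.statistic), k - 1, float(fr.pvalue),
                                 float(fr.statistic / (n * (k - 1))), "kendall_w")
            res.warnings = tuple(res.warnings) + tuple(notes)
            rows.append(_result_row(p, res))
    else:
        raise ValidationError(f"unknown contrast {contrast!r}")
    return pd.DataFrame(rows)


def _result_row(label: str, res: StatResult) -> dict:
    return dict(
        label=label, test_name=res.test_name, statistic=res.statistic,
        df=str(res.df), p=res.p, effect=res.effect, effect_kind=res.effect_kind,
        p_adjusted=res.p_adjusted,
    )
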