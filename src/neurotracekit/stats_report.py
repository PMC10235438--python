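"""Normality-gated test selection, group comparisons and p adjustments.

The reporting conventions mirror common electrophysiology practice: every
group is first screened with Shapiro–Wilk; if normality is rejected
(p < 0.05) in any group, the comparison switches to nonparametric testing
(two-sample Kolmogorov–Smirnov) and summaries are reported as
median ± interquartile range, otherwise a two-tailed t test with mean ± SD.
Multiple-comparison adjustments (Benjamini–Hochberg FDR, Holm, Holm–Šidák,
Bonferroni) are implemented here directly — they are part of this module's
contract — while the underlying distributional tests come from scipy and
the factorial ANOVAs from statsmodels/pingouin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSample",
    "TestResult",
    "normality_gate",
    "compare_two",
    "adjust_p",
    "anova_factorial",
]


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("a group needs at least 2 values")
        if not np.all(np.isfinite(values)):
            raise ValueError("group values must be finite")
        object.__setattr__(self, "values", values)

    def summary(self, mode: str) -> tuple[float, float]:
        """(center, spread): mean ± SD or median ± IQR depending on mode."""
        if mode == "mean_sd":
            return float(self.values.mean()), float(self.values.std(ddof=1))
        q1, med, q3 = np.percentile(self.values, [25, 50, 75])
        return float(med), float(q3 - q1)


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p: float                      # two-tailed
    df: tuple[float, ...] = ()    # degrees of freedom (may be fractional)
    n: tuple[int, ...] = ()
    summary_mode: str = "mean_sd"  # or "median_iqr"
    adjusted_p: float | None = None
    group_summaries: tuple = ()
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p - 1e-12:
            raise ValueError("adjusted p must not be below the raw p")


def normality_gate(groups: list[GroupSample], alpha: float = 0.05) -> str:
    """Choose the test family by Shapiro–Wilk screening of every group.

    Returns ``"nonparametric"`` iff normality is rejected (p < alpha) in any
    group, else ``"parametric"``; ``"indeterminate"`` when any group is too
    small for the test (n < 3) — the caller must then choose explicitly.
    """
    if any(g.values.size < 3 for g in groups):
        return "indeterminate"
    for g in groups:
        if stats.shapiro(g.values).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def compare_two(
    a: GroupSample,
    b: GroupSample,
    mode: str = "auto",
    alpha: float = 0.05,
) -> TestResult:
    """Two-group comparison with the gated reporting conventions.

    ``mode``: ``auto`` (Shapiro-gated choice of t vs KS), ``t`` (two-sample
    two-tailed t test), ``ks`` (two-sample Kolmogorov–Smirnov, exact for
    small samples), or ``ratio_paired_t`` (one-sample t on log ratios of
    paired positive values).  Summaries are mean ± SD for parametric
    reports and median ± IQR for nonparametric ones.
    """
    if mode == "auto":
        gate = normality_gate([a, b], alpha=alpha)
        if gate == "indeterminate":
            raise ValueError("groups too small for the normality gate; pick a mode")
        mode = "t" if gate == "parametric" else "ks"

    na, nb = a.values.size, b.values.size
    if mode == "t":
        res = stats.ttest_ind(a.values, b.values)
        out = TestResult(test="t", statistic=float(res.statistic),
                         p=float(res.pvalue), df=(float(na + nb - 2),),
                         n=(na, nb), summary_mode="mean_sd")
    elif mode == "ks":
        res = stats.ks_2samp(a.values, b.values)
        out = TestResult(test="ks", statistic=float(res.statistic),
                         p=float(res.pvalue), n=(na, nb),
                         summary_mode="median_iqr")
    elif mode == "ratio_paired_t":
        if na != nb:
            raise ValueError("ratio_paired_t requires equal-length paired groups")
        if np.any(a.values <= 0) or np.any(b.values <= 0):
            raise ValueError("ratio_paired_t requires strictly positive values")
        logr = np.log(a.values / b.values)
        if np.ptp(logr) == 0.0:  # degenerate: every pair has the same ratio
            stat, p = (0.0, 1.0) if logr[0] == 0.0 else (np.inf * np.sign(logr[0]), 0.0)
        else:
            res = stats.ttest_1samp(logr, 0.0)
            stat, p = float(res.statistic), float(res.pvalue)
        out = TestResult(test="ratio_paired_t", statistic=stat,
                         p=p, df=(float(na - 1),), n=(na,),
                         summary_mode="mean_sd")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mode_name = out.summary_mode
    return TestResult(**{**out.__dict__,
                         "group_summaries": ((a.label, *a.summary(mode_name)),
                                             (b.label, *b.summary(mode_name)))})


def adjust_p(pvalues, method: str = "BH") -> np.ndarray:
    """Multiple-comparison adjusted p values (same order as the input).

    Methods: ``BH`` (Benjamini–Hochberg step-up FDR), ``holm`` (step-down
    Bonferroni), ``holm_sidak`` (step-down Šidák) and ``bonferroni``.
    Monotonicity is enforced and values are capped at 1; adjusted ≥ raw for
    every method.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.empty(m)
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "BH":
        # step-up: p_(i) * m / i, running minimum from the largest down
        stepped = ranked * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(stepped[::-1])[::-1]
    elif method == "holm":
        # step-down: (m - i + 1) * p_(i), running maximum from the smallest
        stepped = ranked * (m - np.arange(m))
        adj = np.maximum.accumulate(stepped)
    elif method == "holm_sidak":
        stepped = 1.0 - (1.0 - ranked) ** (m - np.arange(m))
        adj = np.maximum.accumulate(stepped)
    else:
        raise ValueError(f"unknown method {method!r}")
    out = np.empty(m)
    out[order] = np.minimum(1.0, adj)
    return out


def anova_factorial(
    table: pd.DataFrame,
    dv: str,
    factors: tuple[str, str],
    repeated: bool = False,
    subject: str | None = None,
    posthoc: str | None = None,
) -> list[TestResult]:
    """Two-factor ANOVA: main effects and interaction.

    For ``repeated=True`` the first factor is within-subject (``subject``
    identifiers required) and the second between-group; the within effect
    carries a Greenhouse–Geisser sphericity correction, so its reported
    degrees of freedom may be fractional.  ``posthoc`` may be ``"tukey"``
    (all pairwise on the second factor) or ``"per_level_bh"``
    (between-group comparison at each level of the first factor, BH-
    adjusted); post hoc results are appended to the returned list.
    """
    f1, f2 = factors
    for col in (dv, f1, f2):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    results: list[TestResult] = []
    if repeated:
        import pingouin as pg

        if subject is None or subject not in table.columns:
            raise ValueError("repeated design needs a subject column")
        n_levels = table[f1].nunique()
        per_subject = table.groupby(subject, observed=True)[f1].nunique()
        if (per_subject != n_levels).any():
            raise ValueError("repeated design has missing cells")
        aov = pg.mixed_anova(table, dv=dv, within=f1, subject=subject,
                             between=f2, correction=True)
        for _, row in aov.iterrows():
            eps = row.get("eps")
            corrected = isinstance(eps, float) and np.isfinite(eps) \
                and not pd.isna(row.get("p_GG_corr", np.nan))
            df1, df2 = float(row["DF1"]), float(row["DF2"])
            if corrected:
                df1, df2 = eps * df1, eps * df2
            p = float(row["p_GG_corr"]) if corrected else float(row["p_unc"])
            results.append(TestResult(
                test=f"rm_anova:{row['Source']}", statistic=float(row["F"]),
                p=min(1.0, p), df=(df1, df2),
                extras={"eps": None if not corrected else float(eps)}))
    else:
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        data = table.rename(columns={dv: "_y", f1: "_f1", f2: "_f2"})
        if data.groupby(["_f1", "_f2"], observed=True)["_y"].count().min() < 2:
            raise ValueError("every factor cell needs at least 2 observations")
        model = ols("_y ~ C(_f1) * C(_f2)", data=data).fit()
        aov = sm.stats.anova_lm(model, typ=2)
        names = {"C(_f1)": f1, "C(_f2)": f2, "C(_f1):C(_f2)": f"{f1}:{f2}"}
        resid_df = float(aov.loc["Residual", "df"])
        for key, name in names.items():
            results.append(TestResult(
                test=f"anova:{name}", statistic=float(aov.loc[key, "F"]),
                p=float(aov.loc[key, "PR(>F)"]),
                df=(float(aov.loc[key, "df"]), resid_df)))

    if posthoc == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tk = pairwise_tukeyhsd(table[dv], table[f2])
        frame = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        for _, row in frame.iterrows():
            results.append(TestResult(
                test=f"tukey:{row['group1']}-vs-{row['group2']}",
                statistic=float(row["meandiff"]), p=float(row["p-adj"])))
    elif posthoc == "per_level_bh":
        levels = sorted(table[f1].unique())
        raw = []
        for lv in levels:
            sub = table[table[f1] == lv]
            gs = [GroupSample(str(g), grp[dv].to_numpy())
                  for g, grp in sub.groupby(f2, observed=True)]
            if len(gs) != 2:
                raise ValueError("per_level_bh post hoc needs exactly 2 groups")
            raw.append(compare_two(gs[0], gs[1], mode="t"))
        adj = adjust_p([r.p for r in raw], method="BH")
        for lv, r, q in zip(levels, raw, adj):
            results.append(TestResult(test=f"per_level:{lv}", statistic=r.statistic,
                                      p=r.p, df=r.df, adjusted_p=float(q)))
    elif posthoc is not None:
        raise ValueError(f"unknown posthoc {posthoc!r}")
    return results
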