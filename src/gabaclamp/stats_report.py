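"""Group-level tabulation and reporting statistics.

The reporting contract mirrors the study's conventions: Shapiro–Wilk decides
between mean ± SEM and median ± IQR presentation; per-feature group
comparisons use a two-way ANOVA over the crossed two-level factors age ×
treatment with type-III sums of squares (the convention of the graphing
software whose "Diff [CI]" style the tables follow) and Šídák-adjusted
pairwise comparisons for the four reported contrasts; the 5 nS spike
comparison uses Welch's unequal-variance t-test.  Response tables count, per
group and condition, the cells whose sweeps were all subthreshold (PSP), all
spiking (AP), or mixed (Both).

ANOVA and the underlying OLS machinery come from statsmodels; the Šídák
adjustment, marginal-difference confidence intervals and tabulation are
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DesignError
from .trace_model import GROUPS

__all__ = [
    "NormalityDecision",
    "normality_check",
    "AnovaResult",
    "two_way_anova",
    "sidak_adjust",
    "welch_t",
    "WelchResult",
    "response_table",
]

#: The four pairwise contrasts reported in the study's tables, as
#: ((age, treatment), (age, treatment)) pairs.
REPORTED_CONTRASTS = (
    (("three_week", "VEH"), ("adult", "VEH")),
    (("three_week", "PNA"), ("adult", "PNA")),
    (("three_week", "VEH"), ("three_week", "PNA")),
    (("adult", "VEH"), ("adult", "PNA")),
)


@dataclass
class NormalityDecision:
    statistic: float  # Shapiro–Wilk W
    p_value: float
    normal: bool
    report_as: str  # "mean±SEM" or "median±IQR"


def normality_check(values, alpha: float = 0.05) -> NormalityDecision:
    """Shapiro–Wilk test and the reporting decision it implies."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DataError("normality check needs at least 3 values")
    if np.ptp(x) == 0:
        raise DataError("constant vector: normality is undefined")
    w, p = stats.shapiro(x)
    normal = p >= alpha
    return NormalityDecision(
        statistic=float(w),
        p_value=float(p),
        normal=normal,
        report_as="mean±SEM" if normal else "median±IQR",
    )


def sidak_adjust(p: float, k: int = 4) -> float:
    """Šídák family-wise adjustment of a single comparison p-value over k
    comparisons: p_adj = 1 − (1 − p)^k."""
    return float(min(1.0, 1.0 - (1.0 - p) ** k))


@dataclass
class AnovaResult:
    """Type-III two-way ANOVA effects and Šídák pairwise comparisons."""

    effects: pd.DataFrame  # index age/treatment/interaction: F, df, p, diff, CI
    pairwise: pd.DataFrame  # the four reported contrasts, Šídák-adjusted
    cell_means: pd.DataFrame
    residual_df: int
    mse: float


def two_way_anova(values, age, treatment, ci_level: float = 0.95) -> AnovaResult:
    """Two-way ANOVA (age × treatment, both two-level, possibly unbalanced).

    Type-III sums of squares with sum-to-zero coding; the effect "difference"
    is the difference of unweighted marginal means with a t-based CI on the
    residual degrees of freedom.  Pairwise comparisons use the pooled
    residual variance and Šídák adjustment over the four reported contrasts.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "age": pd.Categorical(age, categories=["three_week", "adult"]),
            "treatment": pd.Categorical(treatment, categories=["VEH", "PNA"]),
        }
    ).dropna()
    counts = df.groupby(["age", "treatment"], observed=False).size()
    if (counts == 0).any():
        raise DesignError(f"empty design cell(s): {counts[counts == 0].index.tolist()}")

    model = smf.ols("value ~ C(age, Sum) * C(treatment, Sum)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    resid_df = int(model.df_resid)
    mse = float(model.mse_resid)
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, resid_df)

    means = df.groupby(["age", "treatment"], observed=False)["value"].mean()
    ns = counts.astype(float)

    def marginal(factor: str, level: str) -> tuple[float, float]:
        """Unweighted marginal mean over the other factor and its variance
        coefficient Σ 1/n (before the /4 and MSE factors)."""
        sel = [(a, t) for a, t in means.index if (a if factor == "age" else t) == level]
        m = np.mean([means[key] for key in sel])
        vc = sum(1.0 / ns[key] for key in sel)
        return float(m), float(vc)

    rows = {}
    for factor, key, (l1, l2) in (
        ("age", "C(age, Sum)", ("three_week", "adult")),
        ("treatment", "C(treatment, Sum)", ("VEH", "PNA")),
    ):
        m1, v1 = marginal(factor, l1)
        m2, v2 = marginal(factor, l2)
        diff = m1 - m2
        se = np.sqrt(mse * (v1 + v2) / 4.0)
        rows[factor] = {
            "F": float(table.loc[key, "F"]),
            "df_num": int(table.loc[key, "df"]),
            "df_den": resid_df,
            "p": float(table.loc[key, "PR(>F)"]),
            "diff": diff,
            "ci_low": diff - tcrit * se,
            "ci_high": diff + tcrit * se,
        }
    ikey = "C(age, Sum):C(treatment, Sum)"
    inter_diff = float(
        (means[("three_week", "VEH")] - means[("three_week", "PNA")])
        - (means[("adult", "VEH")] - means[("adult", "PNA")])
    )
    se_i = np.sqrt(mse * sum(1.0 / ns[key] for key in means.index))
    rows["interaction"] = {
        "F": float(table.loc[ikey, "F"]),
        "df_num": int(table.loc[ikey, "df"]),
        "df_den": resid_df,
        "p": float(table.loc[ikey, "PR(>F)"]),
        "diff": inter_diff,
        "ci_low": inter_diff - tcrit * se_i,
        "ci_high": inter_diff + tcrit * se_i,
    }
    effects = pd.DataFrame(rows).T

    prows = []
    for (a1, t1), (a2, t2) in REPORTED_CONTRASTS:
        m1, m2 = means[(a1, t1)], means[(a2, t2)]
        se = np.sqrt(mse * (1.0 / ns[(a1, t1)] + 1.0 / ns[(a2, t2)]))
        tval = (m1 - m2) / se
        p_raw = 2.0 * stats.t.sf(abs(tval), resid_df)
        prows.append(
            {
                "contrast": f"{a1} {t1} vs {a2} {t2}",
                "diff": float(m1 - m2),
                "t": float(tval),
                "p_raw": float(p_raw),
                "p_sidak": sidak_adjust(p_raw, k=len(REPORTED_CONTRASTS)),
            }
        )
    pairwise = pd.DataFrame(prows)
    cell_means = pd.DataFrame({"mean": means, "n": counts})
    return AnovaResult(
        effects=effects, pairwise=pairwise, cell_means=cell_means,
        residual_df=resid_df, mse=mse,
    )


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(values_a, values_b) -> WelchResult:
    """Unpaired t-test with Welch's correction (Satterthwaite df)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("Welch's t-test needs at least 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return WelchResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def response_table(cell_labels: dict) -> pd.DataFrame:
    """Per group × condition counts of cells by membrane response.

    ``cell_labels`` maps cell id → (group, {template_id: list of sweep
    labels}).  A cell counts as "PSP" for a condition when no sweep contained
    an AP, "AP" when every non-excluded sweep did, and "Both" for a mixture;
    baseline-failing sweeps do not influence the category.  Percentages are
    recomputed from the counts.
    """
    ap_labels = {"ap_rising", "ap_delayed", "ap_deferred"}
    rows = []
    conditions: list = sorted(
        {tid for _, per_tid in cell_labels.values() for tid in per_tid}
    )
    for group, tid in product([str(g) for g in GROUPS], conditions):
        n_psp = n_ap = n_both = 0
        for _, (g, per_tid) in cell_labels.items():
            if str(g) != group or tid not in per_tid:
                continue
            labels = [l for l in per_tid[tid] if l != "baseline_fail"]
            if not labels:
                continue
            ap = sum(l in ap_labels for l in labels)
            if ap == 0:
                n_psp += 1
            elif ap == len(labels):
                n_ap += 1
            else:
                n_both += 1
        total = n_psp + n_ap + n_both
        rows.append(
            {
                "group": group,
                "condition": tid,
                "PSP": n_psp,
                "AP": n_ap,
                "Both": n_both,
                "total": total,
                "pct_with_ap": 100.0 * (n_ap + n_both) / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)
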