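"""Expansion-rate regression and group-comparison statistics.

Per-replicate time courses are summarized by an ordinary least-squares
slope (metric units per day) or a trapezoidal AUC; groups of replicate
summaries are compared by one-way ANOVA (or an ANCOVA interaction test on
pooled points), with Benjamini-Hochberg FDR correction at 5% across
multiple contrasts, and Brown-Forsythe as the routine homogeneity check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import FitError, ParameterError
from .instability import TimeCourse

#: Floor reported for p values in degenerate zero-within-variance cases.
P_FLOOR = 1e-300

_FDR_METHODS = {"bh": "fdr_bh", "tsbky": "fdr_tsbky"}


@dataclass(frozen=True)
class ExpansionRate:
    """Per-replicate OLS fit of a time-course metric on day."""

    genotype: str
    replicate: str
    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a rate needs >= 2 points")
        if self.slope_se < 0:
            raise ValueError("slope_se must be >= 0")


@dataclass(frozen=True)
class GroupComparison:
    """Result of one statistical contrast (F or t)."""

    statistic: float
    df: tuple[float, float] | float
    p_raw: float
    method: str
    p_adjusted: float | None = None
    degenerate: bool = False


def fit_expansion_rate(course: TimeCourse) -> ExpansionRate:
    """OLS fit of metric on day; exact on collinear input."""
    x = np.asarray(course.days, dtype=float)
    y = np.asarray(course.values, dtype=float)
    if np.unique(x).size < 2:
        raise FitError("all sampling days identical; slope undefined")
    res = stats.linregress(x, y)
    slope_se = 0.0 if not np.isfinite(res.stderr) else float(res.stderr)
    if np.ptp(y) == 0:
        r2 = 1.0  # constant metric is fit exactly by the zero-slope line
    else:
        r2 = float(res.rvalue**2)
    return ExpansionRate(
        genotype=course.genotype,
        replicate=course.replicate,
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=slope_se,
        r_squared=r2,
        n_points=len(x),
    )


def auc(course: TimeCourse) -> float:
    """Trapezoidal area under metric vs day over the observed range."""
    x = np.asarray(course.days, dtype=float)
    y = np.asarray(course.values, dtype=float)
    if np.unique(x).size < 2:
        raise FitError("AUC needs >= 2 distinct days")
    order = np.argsort(x)
    return float(np.trapezoid(y[order], x[order]))


def _validate_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ParameterError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ParameterError("every group needs >= 2 values")
    n_total = sum(a.size for a in arrays)
    if n_total <= len(arrays):
        raise ParameterError("total observations must exceed group count")
    return arrays


def anova_oneway(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """Classical one-way ANOVA F test across groups of replicate values.

    With zero within-group variance and unequal means the F statistic is
    unbounded; the comparison is flagged ``degenerate`` and the p value
    floored at :data:`P_FLOOR` rather than reported as exactly 0.
    """
    arrays = _validate_groups(groups)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    df = (float(k - 1), float(n - k))
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    means = [a.mean() for a in arrays]
    if ssw == 0.0:
        if np.ptp(means) == 0:
            return GroupComparison(0.0, df, 1.0, "one-way ANOVA")
        return GroupComparison(
            float("inf"), df, P_FLOOR, "one-way ANOVA", degenerate=True
        )
    f_stat, p = stats.f_oneway(*arrays)
    return GroupComparison(float(f_stat), df, float(p), "one-way ANOVA")


def brown_forsythe(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """Brown-Forsythe homogeneity-of-variance test: one-way ANOVA on
    absolute deviations from group medians."""
    arrays = _validate_groups(groups)
    transformed = [np.abs(a - np.median(a)) for a in arrays]
    cmp = anova_oneway(transformed)
    return GroupComparison(
        cmp.statistic, cmp.df, cmp.p_raw, "Brown-Forsythe", degenerate=cmp.degenerate
    )


def t_test_independent(
    a: Sequence[float], b: Sequence[float]
) -> GroupComparison:
    """Two-sided equal-variance Student t test, df = n1 + n2 - 2."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("each sample needs >= 2 values")
    df = float(x.size + y.size - 2)
    pooled_ss = float(((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum())
    if pooled_ss == 0.0:
        if x.mean() == y.mean():
            return GroupComparison(0.0, df, 1.0, "independent t")
        return GroupComparison(float("inf"), df, P_FLOOR, "independent t",
                               degenerate=True)
    t_stat, p = stats.ttest_ind(x, y, equal_var=True)
    return GroupComparison(float(t_stat), df, float(p), "independent t")


def fdr_adjust(
    p_values: Sequence[float], q: float = 0.05, method: str = "bh"
) -> tuple[np.ndarray, np.ndarray]:
    """FDR adjustment of p values; returns (adjusted, reject) arrays.

    ``method="bh"`` is Benjamini-Hochberg step-up (default); ``"tsbky"``
    selects the two-stage Benjamini-Krieger-Yekutieli procedure that some
    statistics suites use as their FDR default.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ParameterError("p values must lie in [0, 1]")
    if method not in _FDR_METHODS:
        raise ParameterError(f"method must be one of {sorted(_FDR_METHODS)}")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method=_FDR_METHODS[method])
    return p_adj, reject


def compare_slopes(
    courses: Sequence[TimeCourse], mode: str = "slopes"
) -> GroupComparison:
    """Compare genotype expansion rates.

    ``mode="slopes"`` (default): one-way ANOVA over per-replicate OLS
    slopes, matching a replicate-level unit of analysis.  ``mode="ancova"``:
    F test of the genotype x day interaction in a pooled OLS model of all
    points.
    """
    genotypes = sorted({c.genotype for c in courses})
    if len(genotypes) < 2:
        raise ParameterError("need courses from >= 2 genotypes")
    if mode == "slopes":
        by_geno = {
            g: [fit_expansion_rate(c).slope for c in courses if c.genotype == g]
            for g in genotypes
        }
        return anova_oneway([by_geno[g] for g in genotypes])
    if mode == "ancova":
        import pandas as pd
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rows = [
            {"genotype": c.genotype, "day": d, "value": v}
            for c in courses
            for d, v in c.points
        ]
        df = pd.DataFrame(rows)
        fit = smf.ols("value ~ day * C(genotype)", data=df).fit()
        table = anova_lm(fit, typ=2)
        row = table.loc["day:C(genotype)"]
        return GroupComparison(
            statistic=float(row["F"]),
            df=(float(row["df"]), float(table.loc["Residual", "df"])),
            p_raw=float(row["PR(>F)"]),
            method="ANCOVA interaction",
        )
    raise ParameterError("mode must be 'slopes' or 'ancova'")
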