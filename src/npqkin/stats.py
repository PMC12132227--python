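"""The study's comparison layer.

Assumption checks (Brown-Forsythe homogeneity of variance, Shapiro-Wilk
normality of residuals) gate a natural-log transform; trait effects are
tested by factorial ANOVA (Type II sums of squares, robust to the unbalanced
replicate counts of real experiments); treatments are compared to their
control by two-sided Dunnett many-to-one tests on the equicorrelated
multivariate t; developmental stages by two-sample t-tests; and the
leaf-disc vs whole-plant agreement by ordinary least-squares concordance
regression reporting slope, intercept, adjusted R² and RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


class DegenerateDataError(ValueError):
    """Raised when the data carry no usable variance for a test."""


@dataclass
class AssumptionVerdict:
    """Outcome of the variance-homogeneity and normality screen."""

    brown_forsythe_p: float
    shapiro_p: float
    passed: bool
    transform_recommended: bool
    transformable: bool
    warnings: list[str] = field(default_factory=list)


def assumption_check(values, groups, alpha: float = 0.05) -> AssumptionVerdict:
    """Brown-Forsythe (median-centered Levene) + Shapiro-Wilk on residuals.

    If either test rejects at ``alpha``, a natural-log transform is
    recommended; the transform needs strictly positive values, otherwise the
    verdict is marked untransformable.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 3 for s in samples):
        raise ValueError("need >= 3 values per group")
    if all(np.ptp(s) == 0 for s in samples):
        raise DegenerateDataError("zero within-group variance in every group")
    bf_stat, bf_p = sps.levene(*samples, center="median")
    residuals = np.concatenate([s - s.mean() for s in samples])
    sw_stat, sw_p = sps.shapiro(residuals)
    failed = bf_p < alpha or sw_p < alpha
    transformable = bool((values > 0).all())
    warnings = []
    if failed and not transformable:
        warnings.append("untransformable: non-positive values present")
    return AssumptionVerdict(
        brown_forsythe_p=float(bf_p),
        shapiro_p=float(sw_p),
        passed=not failed,
        transform_recommended=failed,
        transformable=transformable,
        warnings=warnings,
    )


def maybe_log_transform(values, verdict: AssumptionVerdict) -> tuple[np.ndarray, bool]:
    """Apply the natural-log transform when the screen recommends it and the
    data allow it; returns (values, transform_applied)."""
    values = np.asarray(values, dtype=float)
    if verdict.transform_recommended and verdict.transformable:
        return np.log(values), True
    return values, False


def anova_factorial(
    table: pd.DataFrame,
    response: str,
    factors: list[str],
    ss_type: int = 2,
) -> pd.DataFrame:
    """Factorial ANOVA with all interactions on a tidy trait table.

    Type II sums of squares by default (suited to unbalanced designs); Type
    III available via ``ss_type``.  Returns a tidy table with one row per
    term: factor, df, sum_sq, F, p.
    """
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")
    if not factors:
        raise ValueError("need >= 1 factor")
    rhs = " * ".join(f"C({f})" for f in factors)
    model = smf.ols(f"{response} ~ {rhs}", data=table).fit()
    aov = anova_lm(model, typ=ss_type)
    aov = aov.rename(
        columns={"sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p"}
    ).reset_index(names="term")
    return aov


@dataclass
class DunnettRecord:
    group: str
    estimate: float  # mean difference, treatment - control
    statistic: float
    p_adjusted: float


def dunnett_vs_control(
    samples: dict[str, np.ndarray],
    control: str,
    alternative: str = "two-sided",
    seed: int = 0,
) -> list[DunnettRecord]:
    """Two-sided Dunnett many-to-one comparisons against a shared control.

    Adjusted p-values come from the equicorrelated multivariate-t
    distribution implied by the shared control group.  ``seed`` fixes the
    quasi-Monte-Carlo integration of that distribution so repeated calls are
    reproducible.
    """
    if control not in samples:
        raise KeyError(f"control group {control!r} not present")
    treatment_names = [g for g in samples if g != control]
    if not treatment_names:
        raise ValueError("need >= 1 treatment group")
    ctrl = np.asarray(samples[control], dtype=float)
    treats = [np.asarray(samples[g], dtype=float) for g in treatment_names]
    res = sps.dunnett(
        *treats,
        control=ctrl,
        alternative=alternative,
        rng=np.random.default_rng(seed),
    )
    return [
        DunnettRecord(
            group=g,
            estimate=float(t.mean() - ctrl.mean()),
            statistic=float(stat),
            p_adjusted=float(p),
        )
        for g, t, stat, p in zip(treatment_names, treats, res.statistic, res.pvalue)
    ]


@dataclass
class TTestRecord:
    t: float
    p: float
    welch: bool
    flags: list[str] = field(default_factory=list)


def pairwise_t(a, b, alpha: float = 0.05) -> TTestRecord:
    """Two-sided two-sample t-test.

    Pooled-variance by default; falls back to Welch when the Brown-Forsythe
    screen rejects variance homogeneity at ``alpha``.  Two zero-variance
    groups with equal means return t = 0, p = 1 with a flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return TTestRecord(t=0.0, p=1.0, welch=False, flags=["zero_variance"])
        raise DegenerateDataError("zero variance in both groups with unequal means")
    _, bf_p = sps.levene(a, b, center="median")
    welch = bool(bf_p < alpha)
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return TTestRecord(t=float(t), p=float(p), welch=welch)


@dataclass
class RegressionResult:
    """OLS concordance summary: y (leaf disc) regressed on x (whole plant)."""

    slope: float
    intercept: float
    adj_r_squared: float
    rmse: float
    n: int
    p_value: float


def concordance(x, y) -> RegressionResult:
    """Ordinary least squares of paired NPQ series, y on x.

    Used to quantify leaf-disc vs whole-plant agreement: a slope near 1 and
    intercept near 0 with adjusted R² near 1 is the one-to-one regime.
    RMSE is the root mean squared residual.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D series")
    if len(x) < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant x: slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = y - model.fittedvalues
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        adj_r_squared=float(model.rsquared_adj),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n=len(x),
        p_value=float(model.pvalues[1]),
    )
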