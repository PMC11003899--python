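"""Cohort statistics: normality-gated comparisons, correlations, median
split, and the univariate → fully-adjusted regression strategy.

The analysis plan mirrors common practice in clinical morphometry studies:

- every continuous variable is checked for normality (Shapiro-Wilk p ≥ 0.05
  AND |skewness| < 1 — the two diagnostics are combined conjunctively);
- two-group comparisons use Welch's t test when both groups pass the gate,
  otherwise the Wilcoxon-Mann-Whitney rank-sum test;
- categorical traits are compared with Pearson's chi-squared test without
  continuity correction;
- the cohort is split at the median of the outcome (ties go to the low
  group, matching strict "< median" / "> median" group definitions);
- regression screens each candidate covariate in a univariate OLS, admits
  those with p < 0.05 to one multivariable model, and log-transforms the
  outcome and refits when the full model's residuals fail Shapiro-Wilk.

No multiple-testing correction is applied; p < 0.05 is the significance
threshold throughout. Every gate decision is recorded in the returned
result objects so a report can audit the branch taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "NormalityDiagnostics",
    "ComparisonResult",
    "ChiSquaredResult",
    "CorrelationResult",
    "MedianSplitResult",
    "EffectEstimate",
    "CovariateEffect",
    "RegressionResult",
    "normality_gate",
    "compare_groups",
    "chi_squared_test",
    "correlate",
    "median_split",
    "compare_by_median_split",
    "regression_strategy",
]

ALPHA = 0.05
SKEW_LIMIT = 1.0


@dataclass(frozen=True)
class NormalityDiagnostics:
    n: int
    skewness: float
    shapiro_p: float
    is_normal: bool
    degenerate: bool = False


def normality_gate(
    values: Sequence[float], alpha: float = ALPHA, skew_limit: float = SKEW_LIMIT
) -> NormalityDiagnostics:
    """Conjunctive normality decision: Shapiro-Wilk AND bounded skewness.

    A constant vector is degenerate and never normal.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 3:
        raise ValueError("normality check needs at least 3 values")
    if np.ptp(x) == 0:
        return NormalityDiagnostics(
            n=x.size, skewness=0.0, shapiro_p=0.0, is_normal=False, degenerate=True
        )
    shapiro_p = float(sps.shapiro(x).pvalue)
    skew = float(sps.skew(x))
    return NormalityDiagnostics(
        n=x.size,
        skewness=skew,
        shapiro_p=shapiro_p,
        is_normal=(shapiro_p >= alpha) and (abs(skew) < skew_limit),
    )


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    labels: tuple[str, str]
    mean_sd: tuple[tuple[float, float], tuple[float, float]]
    median_iqr: tuple[tuple[float, float], tuple[float, float]]
    test_used: str  # "t" (Welch) | "wilcoxon" (Mann-Whitney rank sum)
    statistic: float
    p_value: float
    normality: tuple[NormalityDiagnostics, NormalityDiagnostics]


def _summaries(x: np.ndarray) -> tuple[tuple[float, float], tuple[float, float]]:
    mean_sd = (float(x.mean()), float(x.std(ddof=1)))
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return mean_sd, (float(med), float(q3 - q1))


def compare_groups(
    x: Sequence[float],
    y: Sequence[float],
    variable: str = "value",
    labels: tuple[str, str] = ("group1", "group2"),
) -> ComparisonResult:
    """Two-sided two-group comparison with the normality gate.

    Welch's t test when both groups pass :func:`normality_gate`, otherwise
    the Wilcoxon-Mann-Whitney rank-sum test. The branch taken is a pure
    function of the two samples.
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.size < 3 or ya.size < 3:
        raise ValueError("both groups need at least 3 values")
    if np.ptp(xa) == 0 and np.ptp(ya) == 0:
        raise ValueError("degenerate groups: both samples are constant")
    gx = normality_gate(xa)
    gy = normality_gate(ya)
    if gx.is_normal and gy.is_normal:
        res = sps.ttest_ind(xa, ya, equal_var=False)
        test = "t"
    else:
        res = sps.mannwhitneyu(xa, ya, alternative="two-sided")
        test = "wilcoxon"
    msx, mix = _summaries(xa)
    msy, miy = _summaries(ya)
    return ComparisonResult(
        variable=variable,
        labels=labels,
        mean_sd=(msx, msy),
        median_iqr=(mix, miy),
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality=(gx, gy),
    )


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    p_value: float
    dof: int
    expected: np.ndarray


def chi_squared_test(table: Sequence[Sequence[float]]) -> ChiSquaredResult:
    """Pearson chi-squared on a contingency table, no continuity correction."""
    t = np.asarray(table, dtype=np.float64)
    if t.ndim != 2:
        raise ValueError("table must be 2-D")
    if (t < 0).any() or not np.allclose(t, np.rint(t)):
        raise ValueError("table must hold non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-squared undefined with a zero marginal")
    stat, p, dof, expected = sps.chi2_contingency(t, correction=False)
    return ChiSquaredResult(
        statistic=float(stat), p_value=float(p), dof=int(dof), expected=expected
    )


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    p_value: float
    n: int


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided p-value."""
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.size != ya.size:
        raise ValueError("x and y must be paired")
    if xa.size < 4:
        raise ValueError("correlation needs at least 4 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a zero-variance variable")
    if method == "pearson":
        res = sps.pearsonr(xa, ya)
    elif method == "spearman":
        res = sps.spearmanr(xa, ya)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return CorrelationResult(
        method=method, r=float(res.statistic), p_value=float(res.pvalue), n=xa.size
    )


@dataclass(frozen=True)
class MedianSplitResult:
    median: float
    low_index: np.ndarray  # boolean, True = low group (value ≤ median)
    high_index: np.ndarray

    @property
    def n_low(self) -> int:
        return int(self.low_index.sum())

    @property
    def n_high(self) -> int:
        return int(self.high_index.sum())


def median_split(values: Sequence[float]) -> MedianSplitResult:
    """Split at the median; ties at the median go to the low group."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("median split needs at least 2 values")
    med = float(np.median(x))
    low = x <= med
    return MedianSplitResult(median=med, low_index=low, high_index=~low)


def compare_by_median_split(
    df: pd.DataFrame,
    split_key: str,
    variables: Sequence[str],
    by_sex: bool = False,
    sex_key: str = "sex",
) -> dict[str, dict[str, ComparisonResult]]:
    """Low-vs-high comparison tables, optionally stratified by sex with
    sex-specific medians (the convention for paired low/high GD tables)."""
    strata: dict[str, pd.DataFrame] = {"all": df}
    if by_sex:
        for sex, sub in df.groupby(sex_key):
            strata[str(sex)] = sub
    out: dict[str, dict[str, ComparisonResult]] = {}
    for name, sub in strata.items():
        split = median_split(sub[split_key].to_numpy())
        rows: dict[str, ComparisonResult] = {}
        for var in variables:
            vals = sub[var].to_numpy(dtype=np.float64)
            rows[var] = compare_groups(
                vals[split.low_index],
                vals[split.high_index],
                variable=var,
                labels=(f"low_{split_key}", f"high_{split_key}"),
            )
        out[name] = rows
    return out


@dataclass(frozen=True)
class EffectEstimate:
    beta: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class CovariateEffect:
    name: str
    unadjusted: EffectEstimate
    adjusted: EffectEstimate | None  # None when not admitted to the full model


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    effects: tuple[CovariateEffect, ...]
    selected: tuple[str, ...]
    log_transformed: bool
    residual_shapiro_p: float | None
    n: int

    def effect(self, name: str) -> CovariateEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


COLLINEARITY_CONDITION_LIMIT = 1e3


def _ols_effect(y: np.ndarray, X: pd.DataFrame, name: str) -> EffectEstimate:
    model = sm.OLS(y, sm.add_constant(X)).fit()
    ci = model.conf_int()
    return EffectEstimate(
        beta=float(model.params[name]),
        ci_low=float(ci.loc[name, 0]),
        ci_high=float(ci.loc[name, 1]),
        p_value=float(model.pvalues[name]),
    )


def regression_strategy(
    df: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    alpha: float = ALPHA,
    condition_limit: float = COLLINEARITY_CONDITION_LIMIT,
) -> RegressionResult:
    """Univariate screen, then one fully adjusted OLS model.

    Each covariate is regressed on its own against the outcome; covariates
    with univariate p < alpha enter the multivariable model. If the full
    model's residuals fail Shapiro-Wilk (p < 0.05) and the outcome is
    strictly positive, the outcome is log-transformed and both the screen's
    admitted model and the full fit are recomputed on the log scale.

    Raises when the admitted covariates are numerically collinear (condition
    number of the standardized design above ``condition_limit``), naming the
    most correlated pair.
    """
    cols = [outcome, *covariates]
    data = df[cols].dropna()
    n = len(data)
    if n < 10 * max(1, len(covariates)) and n < 10:
        raise ValueError("too few complete cases for regression")
    y = data[outcome].to_numpy(dtype=np.float64)

    unadjusted: dict[str, EffectEstimate] = {}
    for cov in covariates:
        unadjusted[cov] = _ols_effect(y, data[[cov]], cov)

    selected = tuple(c for c in covariates if unadjusted[c].p_value < alpha)
    adjusted: dict[str, EffectEstimate] = {}
    resid_p: float | None = None
    log_transformed = False

    if selected:
        X = data[list(selected)]
        if len(selected) > 1:
            Z = (X - X.mean()) / X.std(ddof=0)
            cond = float(np.linalg.cond(Z.to_numpy()))
            if cond > condition_limit:
                corr = X.corr().abs().to_numpy()
                np.fill_diagonal(corr, 0.0)
                i, j = np.unravel_index(np.argmax(corr), corr.shape)
                raise ValueError(
                    f"collinear covariates: {selected[i]!r} and {selected[j]!r} "
                    f"(condition number {cond:.1f})"
                )
        full = sm.OLS(y, sm.add_constant(X)).fit()
        resid_p = float(sps.shapiro(full.resid).pvalue)
        y_fit = y
        if resid_p < ALPHA and (y > 0).all():
            log_transformed = True
            y_fit = np.log(y)
            full = sm.OLS(y_fit, sm.add_constant(X)).fit()
        ci = full.conf_int()
        for cov in selected:
            adjusted[cov] = EffectEstimate(
                beta=float(full.params[cov]),
                ci_low=float(ci.loc[cov, 0]),
                ci_high=float(ci.loc[cov, 1]),
                p_value=float(full.pvalues[cov]),
            )

    effects = tuple(
        CovariateEffect(
            name=cov, unadjusted=unadjusted[cov], adjusted=adjusted.get(cov)
        )
        for cov in covariates
    )
    return RegressionResult(
        outcome=outcome,
        effects=effects,
        selected=selected,
        log_transformed=log_transformed,
        residual_shapiro_p=resid_p,
        n=n,
    )
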