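"""Cohort-level statistics of vessel attenuation.

Welch (unequal-variance) t-tests for sex differences in mean AoHU,
simple linear regressions of AoHU on demographic and scan predictors
(age per decade, weight per 10 kg, vertebral level per step, slice
thickness per mm), and the paired plaque-pixel regression relating
contrast-enhanced to non-contrast attenuation.  Fits delegate to
scipy/statsmodels; results carry adjusted R-squared (which, unlike plain
R-squared, can go negative for uninformative predictors) and two-tier
significance flags.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .plaque import PlaqueHUDistribution

__all__ = [
    "TTestResult",
    "RegressionResult",
    "welch_ttest",
    "simple_regression",
    "plaque_contrast_regression",
    "generate_contrast_pairs",
    "significance_tier",
]


@dataclass(frozen=True)
class TTestResult:
    mean_difference: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class RegressionResult:
    slope: float  # per stated unit
    intercept: float
    adj_r2: float
    p_value: float
    n: int
    unit: str = ""


def significance_tier(p: float) -> str:
    """Two-tier flag: '**' for p < 0.001, '*' for p < 0.01, else ''."""
    if p < 0.001:
        return "**"
    if p < 0.01:
        return "*"
    return ""


def welch_ttest(group_a, group_b) -> TTestResult:
    """Two-tailed t-test assuming unequal variances (Welch-Satterthwaite df).

    Degenerate input with zero variance in both groups and equal means
    returns p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    diff = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
        t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        return TTestResult(diff, float(t), float(a.size + b.size - 2), p, a.size, b.size)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        mean_difference=diff,
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def simple_regression(x, y, unit_scale: float = 1.0, unit: str = "") -> RegressionResult:
    """OLS of y on x; slope reported per ``unit_scale`` units of x.

    e.g. ``unit_scale=10`` with x in years reports HU per decade, and
    with x in kg reports HU per 10 kg.  The slope p-value is the usual
    t-test against zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; slope is undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1] * unit_scale),
        intercept=float(model.params[0]),
        adj_r2=float(model.rsquared_adj),
        p_value=float(model.pvalues[1]),
        n=int(x.size),
        unit=unit,
    )


def plaque_contrast_regression(x_noncontrast, y_contrast) -> RegressionResult:
    """OLS of paired plaque pixel HU: contrast-enhanced on non-contrast.

    Used to check that contrast does not materially alter calcified
    pixel attenuation (slope near 1, small intercept, high adjusted R2).
    """
    x = np.asarray(x_noncontrast, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 paired plaque pixels")
    return simple_regression(x, y_contrast, unit_scale=1.0, unit="HU per HU")


def generate_contrast_pairs(
    plaque_law: PlaqueHUDistribution,
    n: int,
    rng: np.random.Generator,
    slope: float = 1.1,
    intercept: float = 2.7,
    target_adj_r2: float = 0.97,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic paired plaque pixels under a linear contrast relation.

    x is drawn from the plaque law; y = slope*x + intercept + e with the
    noise SD chosen so the population R-squared equals the target:
    SD(e) = slope * SD(x) * sqrt((1 - R2)/R2).
    """
    if not 0.0 < target_adj_r2 < 1.0:
        raise ValueError("target adjusted R2 must lie in (0, 1)")
    x = plaque_law.sample(n, rng)
    noise_sd = abs(slope) * x.std(ddof=1) * np.sqrt((1.0 - target_adj_r2) / target_adj_r2)
    y = slope * x + intercept + rng.normal(0.0, noise_sd, size=n)
    return x, y
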