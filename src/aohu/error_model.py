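"""Expected false-positive / false-negative rates of plaque thresholds.

Under the model that non-plaque pixel attenuation inside a vessel is
Normal(mean AoHU, SD AoHU), the false-positive rate of a HU cutoff T in
one scan is the normal tail

    FP(T) = 1 - Phi((T - mean) / SD).

A dynamic cutoff at mean + N.SD therefore yields FP = 1 - Phi(N) in
*every* scan, regardless of its enhancement (1 - Phi(3) = 0.00135, i.e.
0.13% of vessel pixels).  For a cohort whose scan means are themselves
Normal(M, S) with shared within-scan SD sigma, the scan-averaged FP of a
uniform cutoff has the closed form

    FP_pop(T) = 1 - Phi((T - M) / sqrt(S^2 + sigma^2)),

the Gaussian convolution of between-scan and within-scan spread.

The false-negative rate of a cutoff is the plaque-attenuation CDF at the
cutoff: the fraction of true plaque pixels too faint to clear it.  Under
a dynamic scheme it is averaged over the per-scan cutoffs mean_i + N.sd_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .plaque import PlaqueHUDistribution

__all__ = [
    "PopulationModel",
    "ErrorEstimate",
    "fp_rate_scan",
    "fp_rate_population",
    "fp_rate_population_mc",
    "fn_rate",
    "fn_rate_dynamic",
    "error_curves",
    "min_threshold_for_fp",
]


@dataclass(frozen=True)
class PopulationModel:
    """Cohort of scans, parametric or explicit.

    Parametric: scan means ~ Normal(M, S) with shared within-scan pixel
    SD ``sigma_bar``.  Explicit: a list of per-scan (mean, SD) pairs;
    set ``scans`` and leave the parametric fields None.
    """

    M: float | None = None
    S: float | None = None
    sigma_bar: float | None = None
    scans: tuple[tuple[float, float], ...] | None = None
    phase: str = ""

    def __post_init__(self) -> None:
        if self.scans is not None:
            if len(self.scans) == 0:
                raise ValueError("explicit scan list must be non-empty")
            if any(sd <= 0 for _, sd in self.scans):
                raise ValueError("every scan SD must be positive")
        else:
            if self.M is None or self.S is None or self.sigma_bar is None:
                raise ValueError("parametric model requires M, S and sigma_bar")
            if self.S < 0:
                raise ValueError("S must be >= 0")
            if self.sigma_bar <= 0:
                raise ValueError("sigma_bar must be positive")

    @property
    def is_parametric(self) -> bool:
        return self.scans is None

    @property
    def n_scans(self) -> int | None:
        return None if self.is_parametric else len(self.scans)


@dataclass(frozen=True)
class ErrorEstimate:
    threshold: float  # T in HU, or N in SD units
    scheme: str  # "uniform" | "dynamic"
    fp_rate: float
    fn_rate: float
    phase: str = ""
    n_scans: int | None = None


def fp_rate_scan(mean_AoHU, sd_AoHU, threshold_HU):
    """Single-scan normal-tail false-positive rate 1 - Phi((T - m)/sd)."""
    sd = np.asarray(sd_AoHU, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd_AoHU must be positive")
    out = norm.sf((np.asarray(threshold_HU, dtype=float) - np.asarray(mean_AoHU, dtype=float)) / sd)
    return float(out) if out.ndim == 0 else out


def fp_rate_population(pop: PopulationModel, threshold_HU: float) -> float:
    """Scan-averaged FP of a uniform cutoff (each scan weighted equally).

    Parametric populations use the Gaussian-convolution closed form;
    explicit scan lists average the per-scan tails exactly.
    """
    if pop.is_parametric:
        return float(norm.sf((threshold_HU - pop.M) / np.hypot(pop.S, pop.sigma_bar)))
    means = np.array([m for m, _ in pop.scans])
    sds = np.array([s for _, s in pop.scans])
    return float(np.mean(fp_rate_scan(means, sds, threshold_HU)))


def fp_rate_population_mc(
    pop: PopulationModel, threshold_HU: float, n_scans: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo check of the closed form: draw scan means, average tails."""
    if not pop.is_parametric:
        return fp_rate_population(pop, threshold_HU)
    means = rng.normal(pop.M, pop.S, size=n_scans)
    return float(np.mean(fp_rate_scan(means, pop.sigma_bar, threshold_HU)))


def fn_rate(plaque: PlaqueHUDistribution, threshold_HU) -> float | np.ndarray:
    """Fraction of true plaque pixels below the cutoff: the plaque CDF."""
    return plaque.cdf(threshold_HU)


def fn_rate_dynamic(
    plaque: PlaqueHUDistribution,
    pop: PopulationModel,
    N: float,
    n_mc: int = 100_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Expected FN of the dynamic mean + N.SD scheme over a population.

    Explicit scan lists are averaged exactly; parametric populations by
    Monte-Carlo over scan means (seeded ``rng`` for reproducibility).
    """
    if not pop.is_parametric:
        cuts = np.array([m + N * sd for m, sd in pop.scans])
        return float(np.mean(plaque.cdf(cuts)))
    rng = rng if rng is not None else np.random.default_rng(0)
    means = rng.normal(pop.M, pop.S, size=n_mc)
    return float(np.mean(plaque.cdf(means + N * pop.sigma_bar)))


def error_curves(
    plaque: PlaqueHUDistribution,
    pops: dict[str, PopulationModel],
    uniform_grid=None,
    dynamic_grid=None,
    n_mc: int = 100_000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """FP and FN along threshold grids per phase group.

    Returns a tidy frame with columns scheme, phase, threshold_or_N, fp,
    fn, n_scans, sigma_bar.  Monotonicity (FP non-increasing, FN
    non-decreasing along each grid) is verified as a post-condition.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    for phase, pop in pops.items():
        if uniform_grid is not None:
            for T in uniform_grid:
                rows.append(
                    {
                        "scheme": "uniform",
                        "phase": phase,
                        "threshold_or_N": float(T),
                        "fp": fp_rate_population(pop, T),
                        "fn": float(fn_rate(plaque, T)),
                        "n_scans": pop.n_scans,
                        "sigma_bar": pop.sigma_bar,
                    }
                )
        if dynamic_grid is not None:
            for N in dynamic_grid:
                rows.append(
                    {
                        "scheme": "dynamic",
                        "phase": phase,
                        "threshold_or_N": float(N),
                        "fp": _dynamic_fp(pop, N),
                        "fn": fn_rate_dynamic(plaque, pop, N, n_mc=n_mc, rng=rng),
                        "n_scans": pop.n_scans,
                        "sigma_bar": pop.sigma_bar,
                    }
                )
    curves = pd.DataFrame(rows)
    for (scheme, phase), grp in curves.groupby(["scheme", "phase"]):
        grp = grp.sort_values("threshold_or_N")
        if np.any(np.diff(grp["fp"].to_numpy()) > 1e-12):
            raise AssertionError(f"FP not non-increasing for {scheme}/{phase}")
        if np.any(np.diff(grp["fn"].to_numpy()) < -1e-12):
            raise AssertionError(f"FN not non-decreasing for {scheme}/{phase}")
    return curves


def _dynamic_fp(pop: PopulationModel, N: float) -> float:
    """Dynamic FP is 1 - Phi(N) in every scan, hence also on average."""
    return float(norm.sf(N))


def min_threshold_for_fp(pop: PopulationModel, target_fp: float) -> float:
    """Smallest uniform cutoff whose population FP is <= target.

    Parametric: closed form M + z.sqrt(S^2 + sigma^2), z = Phi^-1(1 - target).
    Explicit lists: bisection on the (monotone) population FP; an
    unreachable target returns the bracket boundary with a warning.
    """
    if not 0.0 < target_fp < 1.0:
        raise ValueError("target_fp must lie strictly in (0, 1)")
    if pop.is_parametric:
        return float(pop.M + norm.isf(target_fp) * np.hypot(pop.S, pop.sigma_bar))
    means = np.array([m for m, _ in pop.scans])
    sds = np.array([s for _, s in pop.scans])
    lo = float((means - 8 * sds).min())
    hi = float((means + 8 * sds).max())
    f = lambda T: fp_rate_population(pop, T) - target_fp
    if f(hi) > 0:
        import warnings

        warnings.warn("target FP unreachable on this scan list; returning upper boundary", stacklevel=2)
        return hi
    if f(lo) < 0:
        return lo
    return float(brentq(f, lo, hi, xtol=1e-6))
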