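"""Attenuation law for calcified-plaque pixels.

Calcified plaque detected on non-contrast CT at the classical 130 HU
threshold shows a right-skewed attenuation distribution: a hard lower edge
at the detection threshold, a median a little above 250 HU, and a long
tail reaching well past 1000 HU.  We model this as a shifted log-normal,

    X = offset + exp(Z),   Z ~ Normal(ln(median - offset), s^2),

with the log-scale ``s`` solved so that the untruncated 99th percentile
sits at a prescribed upper value, and samples above that percentile
censored (clipped) to it.  Censoring rather than rejection keeps the
median and every quantile below the cap exactly where the two-point
calibration puts them.

The analytic CDF of this law is the expected false-negative rate of a
uniform HU threshold: the fraction of true plaque pixels whose
attenuation falls below the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = ["PlaqueHUDistribution", "make_plaque_law"]


@dataclass(frozen=True)
class PlaqueHUDistribution:
    """Shifted, upper-censored log-normal law for plaque pixel HU.

    Parameters are the three printed summaries of the empirical
    distribution: the detection threshold (``offset_HU``, the hard
    minimum), the median, and the ~99th-percentile maximum.  ``sigma_log``
    is derived, not free.
    """

    offset_HU: float
    median_HU: float
    p99_HU: float
    sigma_log: float = field(init=False)
    mu_log: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.offset_HU < self.median_HU < self.p99_HU):
            raise ValueError(
                "require offset < median < p99, got "
                f"({self.offset_HU}, {self.median_HU}, {self.p99_HU})"
            )
        mu = np.log(self.median_HU - self.offset_HU)
        s = np.log((self.p99_HU - self.offset_HU) / (self.median_HU - self.offset_HU))
        s /= norm.ppf(0.99)
        object.__setattr__(self, "mu_log", float(mu))
        object.__setattr__(self, "sigma_log", float(s))

    @property
    def min_HU(self) -> float:
        return self.offset_HU

    def cdf(self, hu) -> np.ndarray | float:
        """P(X <= hu); 0 at and below the offset, 1 at and above the cap."""
        hu = np.asarray(hu, dtype=float)
        out = np.zeros_like(hu)
        above = hu > self.offset_HU
        with np.errstate(divide="ignore"):
            z = (np.log(np.where(above, hu - self.offset_HU, 1.0)) - self.mu_log) / self.sigma_log
        out = np.where(above, norm.cdf(z), 0.0)
        out = np.where(hu >= self.p99_HU, 1.0, out)  # censored mass at the cap
        return out if out.ndim else float(out)

    def ppf(self, q) -> np.ndarray | float:
        """Quantile function; inverse of :meth:`cdf` on (0, 0.99)."""
        q = np.asarray(q, dtype=float)
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("quantile levels must lie strictly in (0, 1)")
        x = self.offset_HU + np.exp(self.mu_log + self.sigma_log * norm.ppf(q))
        x = np.minimum(x, self.p99_HU)
        return x if x.ndim else float(x)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        draws = self.offset_HU + np.exp(rng.normal(self.mu_log, self.sigma_log, size=n))
        return np.minimum(draws, self.p99_HU)


def make_plaque_law(
    offset_HU: float = 130.0,
    median_HU: float = 256.0,
    p99_HU: float = 1400.0,
) -> PlaqueHUDistribution:
    """Calibrate the plaque HU law to (offset, median, upper-percentile).

    Defaults reproduce the printed summary of plaque pixels segmented at
    130 HU on non-contrast scans: range 130-1400 HU, median 256 HU.
    """
    return PlaqueHUDistribution(offset_HU=offset_HU, median_HU=median_HU, p99_HU=p99_HU)
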