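"""Box–Cox Cole–Green (BCCG) distribution: the mathematics behind LMS centiles.

The LMS method summarises an age-varying, positively skewed measurement by
three parameters: the Box–Cox power ``lam`` (L, skewness), the median ``mu``
(M) and the coefficient of variation ``sigma`` (S).  A measurement ``y`` is
mapped to a standard-normal deviate by

    z = ((y / mu)**lam - 1) / (lam * sigma)      for lam != 0
    z = log(y / mu) / sigma                      for lam == 0

and the centile at percentile rank ``p`` is the inverse map evaluated at the
standard-normal quantile ``z_p``:

    C(p) = mu * (1 + lam * sigma * z_p)**(1 / lam)   for lam != 0
    C(p) = mu * exp(sigma * z_p)                     for lam == 0

Everything else in this package (reference tables, zone cut-offs, the
penalized-likelihood fit) is built on these transforms.

The small probability mass the Box–Cox transform places below y = 0 is
ignored in the density and likelihood, as is standard in LMS practice; for
sigma <= 0.5 the neglected mass is far below any tolerance used here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LAMBDA_EPS",
    "LMSTriple",
    "Percentile",
    "bccg_quantile",
    "bccg_zscore",
    "bccg_logdensity",
    "bccg_sample",
]

#: |lam| below this threshold switches to the log (lam -> 0) branch; the
#: singularity at lam = 0 is removable and both branches agree to ~1e-9
#: relative at the switch point.
LAMBDA_EPS = 1e-7

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class LMSTriple:
    """The (L, M, S) parameter set of a BCCG distribution at one age/sex point.

    Attributes
    ----------
    lam:
        Box–Cox skewness power (dimensionless; 1 = Gaussian, 0 = log-normal).
    mu:
        Median of the distribution (kg, > 0).
    sigma:
        Coefficient of variation (dimensionless, > 0).
    """

    lam: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.lam):
            raise ValueError(f"lam must be finite, got {self.lam}")
        if not (self.mu > 0 and math.isfinite(self.mu)):
            raise ValueError(f"mu must be positive and finite, got {self.mu}")
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValueError(f"sigma must be positive and finite, got {self.sigma}")


@dataclass(frozen=True)
class Percentile:
    """A percentile rank in (0, 100) together with its normal deviate z.

    ``z`` is always derived from ``p`` at full double precision (never from
    rounded tabled constants): z(50) = 0 and z(p) = -z(100 - p).
    """

    p: float
    z: float

    @classmethod
    def from_rank(cls, p: float) -> "Percentile":
        if not 0.0 < p < 100.0:
            raise ValueError(f"percentile rank must lie in (0, 100), got {p}")
        return cls(p=float(p), z=float(stats.norm.ppf(p / 100.0)))


def _as_percentile(p: "Percentile | float") -> Percentile:
    if isinstance(p, Percentile):
        return p
    return Percentile.from_rank(float(p))


def bccg_quantile(lms: LMSTriple, p: "Percentile | float") -> float:
    """Centile value C(p) of the BCCG distribution, in measurement units (kg).

    Parameters
    ----------
    lms:
        The (lam, mu, sigma) triple.
    p:
        Percentile rank in (0, 100), or a :class:`Percentile`.

    Raises
    ------
    ValueError
        If ``1 + lam * sigma * z <= 0``: the requested centile does not exist
        for this parameter combination (the Box–Cox transform runs out of
        positive support in that tail).
    """
    pct = _as_percentile(p)
    lam, mu, sigma = lms.lam, lms.mu, lms.sigma
    if abs(lam) < LAMBDA_EPS:
        return mu * math.exp(sigma * pct.z)
    base = 1.0 + lam * sigma * pct.z
    if base <= 0.0:
        raise ValueError(
            f"percentile P{pct.p:g} undefined for triple "
            f"(lam={lam}, mu={mu}, sigma={sigma}): 1 + lam*sigma*z = {base:.6g} <= 0"
        )
    return mu * base ** (1.0 / lam)


def bccg_zscore(y: float, lms: LMSTriple) -> float:
    """LMS z-score of a measurement ``y`` under the triple (inverse of the quantile).

    Raises ``ValueError`` for y <= 0 (the distribution has positive support).
    """
    if not y > 0:
        raise ValueError(f"measurement must be positive, got {y}")
    lam, mu, sigma = lms.lam, lms.mu, lms.sigma
    if abs(lam) < LAMBDA_EPS:
        return math.log(y / mu) / sigma
    return ((y / mu) ** lam - 1.0) / (lam * sigma)


def bccg_logdensity(y: float, lms: LMSTriple) -> float:
    """Log-density of the BCCG distribution at ``y`` (> 0).

    Assembled from the Gaussian kernel in z and the Jacobian of the Box–Cox
    transform:

        log f(y) = (lam - 1) log(y/mu) - log(mu * sigma) - log sqrt(2 pi) - z^2 / 2

    The truncation constant for the sub-zero mass is ignored (see module
    docstring); the density therefore integrates to 1 only up to that
    negligible mass.
    """
    if not y > 0:
        raise ValueError(f"measurement must be positive, got {y}")
    z = bccg_zscore(y, lms)
    lam, mu, sigma = lms.lam, lms.mu, lms.sigma
    return (lam - 1.0) * math.log(y / mu) - math.log(mu * sigma) - _LOG_SQRT_2PI - 0.5 * z * z


def _z_support(lms: LMSTriple) -> tuple[float, float]:
    """Open interval of z values for which the quantile exists."""
    lam, sigma = lms.lam, lms.sigma
    if abs(lam) < LAMBDA_EPS:
        return (-np.inf, np.inf)
    bound = -1.0 / (lam * sigma)
    if lam > 0:
        return (bound, np.inf)
    return (-np.inf, bound)


def bccg_sample(lms: LMSTriple, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` values by inverse-transforming uniforms through the quantile.

    For lam != 0 the BCCG support truncates one normal tail (where
    1 + lam*sigma*z <= 0); uniforms are drawn inside the corresponding
    probability range, i.e. from the properly truncated distribution.  For
    the parameter ranges used in practice (sigma <= 0.5) the truncated mass
    is < 1e-4.
    """
    lo_z, hi_z = _z_support(lms)
    # Stay strictly inside the support; the margin keeps the power finite.
    u_lo = stats.norm.cdf(lo_z) + 1e-12 if np.isfinite(lo_z) else 0.0
    u_hi = stats.norm.cdf(hi_z) - 1e-12 if np.isfinite(hi_z) else 1.0
    u = rng.uniform(u_lo, u_hi, size=n)
    z = stats.norm.ppf(u)
    lam, mu, sigma = lms.lam, lms.mu, lms.sigma
    if abs(lam) < LAMBDA_EPS:
        return mu * np.exp(sigma * z)
    return mu * (1.0 + lam * sigma * z) ** (1.0 / lam)
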