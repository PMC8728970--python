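"""Beta-binomial model of observed cell-type proportions.

A study arm is described by the number of biological samples ``m``, the
number of cells assayed per sample ``n``, and the mean ``mu`` and standard
deviation ``sigma`` of the *true* (biological) cell-type proportion across
subjects.  The true proportion of subject ``j`` is modeled as
``p_j ~ Beta(a, b)`` and the observed cell count as
``A_j | p_j ~ Binomial(n, p_j)``, so the observed proportion ``A_j / n``
follows a scaled beta-binomial distribution.  This module handles the
(mu, sigma) -> (a, b) reparametrization, the moments of the observed
proportion, and normal-approximation diagnostics used to decide whether a
t-test on sample means is trustworthy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GroupSpec",
    "ProportionMoments",
    "shape_from_mean_sd",
    "beta_binomial_moments",
    "observed_proportion_moments",
    "normality_diagnostics",
]

#: relative tolerance for moment round-trip invariant checks
_RTOL = 1e-9


def shape_from_mean_sd(mu: float, sigma: float) -> tuple[float, float]:
    """Beta shape parameters matching a target mean and standard deviation.

    Solves the moment equations ``a / (a + b) = mu`` and
    ``a b / ((a + b)^2 (a + b + 1)) = sigma^2`` for ``(a, b)``:

        a = mu * (mu (1 - mu) / sigma^2 - 1),   b = a (1 / mu - 1).

    Parameters
    ----------
    mu : float
        Mean proportion, strictly in (0, 1).
    sigma : float
        Standard deviation of the proportion, with
        ``0 < sigma^2 < mu (1 - mu)``.

    Returns
    -------
    (a, b) : tuple of float
        Beta shape parameters, both required to exceed 1 so that the
        prior on the true proportion is unimodal.

    Raises
    ------
    ValueError
        If ``mu`` or ``sigma`` violates the variance bound, or if the
        implied shape parameters do not both exceed 1.
    """
    if not (0.0 < mu < 1.0):
        raise ValueError(f"mean proportion mu={mu!r} must lie strictly in (0, 1)")
    if not sigma > 0.0:
        raise ValueError(f"sigma={sigma!r} must be positive")
    bound = mu * (1.0 - mu)
    if sigma * sigma >= bound:
        raise ValueError(
            f"sigma^2={sigma * sigma:.6g} must be below the beta variance bound "
            f"mu*(1-mu)={bound:.6g} (mu={mu:g})"
        )
    concentration = bound / (sigma * sigma) - 1.0  # a + b
    a = mu * concentration
    b = (1.0 - mu) * concentration
    if a <= 1.0 or b <= 1.0:
        raise ValueError(
            f"implied beta shapes a={a:.4g}, b={b:.4g} must both exceed 1 "
            f"(unimodal prior); decrease sigma or move mu away from the boundary"
        )
    return a, b


@dataclass(frozen=True)
class GroupSpec:
    """One arm of a two-group study design.

    Attributes
    ----------
    m : int
        Number of biological samples (subjects) in the arm, >= 2.
    n : int
        Number of cells assayed per sample, >= 1.
    mu : float
        Mean of the true cell-type proportion across subjects.
    sigma : float
        Between-subject standard deviation of the true proportion.
    a, b : float
        Derived beta shape parameters (computed; do not pass).
    """

    m: int
    n: int
    mu: float
    sigma: float
    a: float = field(init=False)
    b: float = field(init=False)

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 2:
            raise ValueError(f"sample count m={self.m!r} must be an integer >= 2")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"cells per sample n={self.n!r} must be an integer >= 1")
        a, b = shape_from_mean_sd(self.mu, self.sigma)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def beta_variance(self) -> float:
        """Variance of the true proportion (the infinite-cell limit), = sigma^2."""
        s = self.a + self.b
        return self.a * self.b / (s * s * (s + 1.0))

    def with_mean(self, mu: float) -> "GroupSpec":
        """Copy of this arm with the mean replaced (sigma unchanged)."""
        return GroupSpec(m=self.m, n=self.n, mu=mu, sigma=self.sigma)

    def with_m(self, m: int) -> "GroupSpec":
        """Copy of this arm with the sample count replaced."""
        return GroupSpec(m=m, n=self.n, mu=self.mu, sigma=self.sigma)

    def with_n(self, n: int) -> "GroupSpec":
        """Copy of this arm with the cells-per-sample replaced."""
        return GroupSpec(m=self.m, n=n, mu=self.mu, sigma=self.sigma)


@dataclass(frozen=True)
class ProportionMoments:
    """Moments of the observed proportion A/n of a single sample."""

    mean: float
    variance: float
    skewness: float
    excess_kurtosis: float


def beta_binomial_moments(n: int, a: float, b: float) -> tuple[float, float, float, float]:
    """Mean, variance, skewness and excess kurtosis of BetaBinomial(n, a, b).

    Standard closed forms.  Skewness and excess kurtosis are standardized
    moments and therefore shared by the count ``A`` and the scaled
    proportion ``A / n``; the mean and variance returned here are those of
    the count.
    """
    s = a + b
    mean = n * a / s
    var = n * a * b * (s + n) / (s * s * (s + 1.0))
    skew = (s + 2.0 * n) * (b - a) / (s + 2.0) * math.sqrt(
        (1.0 + s) / (n * a * b * (n + s))
    )
    # excess kurtosis of the beta-binomial count (standard closed form)
    pref = s * s * (1.0 + s) / (n * a * b * (s + 2.0) * (s + 3.0) * (s + n))
    inner = (
        s * (s - 1.0 + 6.0 * n)
        + 3.0 * a * b * (n - 2.0)
        + 6.0 * n * n
        - 3.0 * a * b * n * (6.0 - n) / s
        - 18.0 * a * b * n * n / (s * s)
    )
    kurt = pref * inner - 3.0
    return mean, var, skew, kurt


def _moments_by_enumeration(n: int, a: float, b: float) -> tuple[float, float, float, float]:
    """Exact moments by summing the beta-binomial pmf over 0..n.

    Fallback for parameter regimes where the closed forms lose precision;
    also the independent oracle used in the test suite.
    """
    from scipy.stats import betabinom

    k = np.arange(n + 1)
    p = betabinom.pmf(k, n, a, b)
    mean = float(np.sum(k * p))
    c = k - mean
    var = float(np.sum(c**2 * p))
    sd = math.sqrt(var)
    skew = float(np.sum(c**3 * p)) / sd**3
    kurt = float(np.sum(c**4 * p)) / var**2 - 3.0
    return mean, var, skew, kurt


def observed_proportion_moments(g: GroupSpec) -> ProportionMoments:
    """Moments of the observed proportion ``A/n`` for one sample of arm ``g``.

    The variance ``a b (a + b + n) / (n (a + b)^2 (a + b + 1))`` exceeds the
    infinite-cell (pure beta) variance ``sigma^2`` for every finite ``n``
    and converges to it as ``n`` grows: finite cell counts inflate the
    spread of observed proportions.
    """
    count_mean, count_var, skew, kurt = beta_binomial_moments(g.n, g.a, g.b)
    if not (math.isfinite(skew) and math.isfinite(kurt)) and g.n < 100:
        count_mean, count_var, skew, kurt = _moments_by_enumeration(g.n, g.a, g.b)
    return ProportionMoments(
        mean=count_mean / g.n,
        variance=count_var / (g.n * g.n),
        skewness=skew,
        excess_kurtosis=kurt,
    )


def normality_diagnostics(g: GroupSpec) -> tuple[float, float, bool]:
    """Assess whether the mean of ``m`` observed proportions is near-normal.

    Averaging ``m`` independent samples shrinks the skewness of the mean by
    ``sqrt(m)`` and its excess kurtosis by ``m``.  Both shrunk magnitudes
    below 0.5 is taken as sufficient normality for the t-approximation.

    Returns
    -------
    (skew_of_mean, kurt_of_mean, normal_ok)
        Absolute skewness of the sample mean, absolute excess kurtosis of
        the sample mean, and whether both fall below 0.5.
    """
    mom = observed_proportion_moments(g)
    skew_of_mean = abs(mom.skewness) / math.sqrt(g.m)
    kurt_of_mean = abs(mom.excess_kurtosis) / g.m
    return skew_of_mean, kurt_of_mean, (skew_of_mean < 0.5 and kurt_of_mean < 0.5)
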