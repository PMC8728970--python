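"""Closed-form false-negative-rate (type-II error) computation.

The engine predicts the distribution of the two-sample t statistic when
each observed proportion follows the scaled beta-binomial model: under the
alternative, ``t`` is approximately a central t shifted by the
noncentrality ``ncp = (E[p1] - E[p0]) / sqrt(V[p1]/m1 + V[p0]/m0)`` (with
model rather than sample moments), so the false-negative rate is the
central-t CDF evaluated at ``t* - ncp``.  The exact noncentral-t CDF is
available as an alternative convention (``cdf_mode='noncentral_t'``), the
one used by classical power software; the two agree closely for moderate
noncentrality.

Variants: unpaired Welch, paired (with correlation ``rho`` of the true
proportions between conditions), the legacy infinite-cell calculation that
ignores finite-cell sampling noise, a SESOI mean-shift helper, and TOST
equivalence power.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

from scipy import stats

from .model import GroupSpec, observed_proportion_moments

__all__ = [
    "TestSpec",
    "PowerResult",
    "welch_df",
    "fnr_unpaired",
    "fnr_legacy",
    "paired_cov",
    "fnr_paired",
    "apply_sesoi",
    "tost_power",
]


@dataclass(frozen=True)
class TestSpec:
    """Hypothesis-test configuration.

    Attributes
    ----------
    alpha : float
        Significance level (false-positive rate), in (0, 1).
    sides : {'one_sided', 'two_sided'}
        Sidedness.  One-sided tests assume the case mean exceeds the
        control mean; the user encodes the hypothesized direction by
        group assignment.
    design : {'unpaired', 'paired'}
    rho : float or None
        Correlation of the *true* proportions between conditions; paired
        designs only.
    sesoi : float
        Smallest effect size of interest — a margin by which the control
        mean is translated before testing, so only differences beyond it
        count.  Default 0 (plain test).
    cdf_mode : {'shifted_central_t', 'noncentral_t'}
        How the alternative distribution of t is evaluated.
    """

    __test__ = False  # keep pytest from collecting this as a test class

    alpha: float = 0.05
    sides: str = "one_sided"
    design: str = "unpaired"
    rho: float | None = None
    sesoi: float = 0.0
    cdf_mode: str = "shifted_central_t"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha={self.alpha!r} must lie in (0, 1)")
        if self.sides not in ("one_sided", "two_sided"):
            raise ValueError(f"sides={self.sides!r} must be 'one_sided' or 'two_sided'")
        if self.design not in ("unpaired", "paired"):
            raise ValueError(f"design={self.design!r} must be 'unpaired' or 'paired'")
        if self.cdf_mode not in ("shifted_central_t", "noncentral_t"):
            raise ValueError(f"unknown cdf_mode {self.cdf_mode!r}")
        if self.design == "unpaired":
            if self.rho is not None:
                raise ValueError("rho is only meaningful for a paired design")
        else:
            rho = 0.0 if self.rho is None else self.rho
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"rho={rho!r} must lie in [-1, 1]")
        if not 0.0 <= self.sesoi < 1.0:
            raise ValueError(f"sesoi={self.sesoi!r} must lie in [0, 1)")


@dataclass(frozen=True)
class PowerResult:
    """Analytic type-II-error output.

    ``beta`` is the false-negative rate, ``power = 1 - beta``, ``ncp`` the
    noncentrality (expected shift of t under the alternative), ``df`` the
    (real-valued) degrees of freedom, ``tcrit`` the critical value.
    """

    beta: float
    ncp: float
    df: float
    tcrit: float

    @property
    def power(self) -> float:
        return 1.0 - self.beta


def welch_df(v0: float, v1: float, m0: int, m1: int) -> float:
    """Welch–Satterthwaite degrees of freedom from per-group model variances.

    Equals ``m0 + m1 - 2`` (the Student case) when the variances and group
    sizes coincide, and drops toward ``min(m0, m1) - 1`` when one group's
    variance term dominates.
    """
    if m0 < 2 or m1 < 2:
        raise ValueError("Welch degrees of freedom require at least 2 samples per group")
    if v0 <= 0.0 or v1 <= 0.0:
        raise ValueError("variances must be positive")
    w0, w1 = v0 / m0, v1 / m1
    return (w0 + w1) ** 2 / (w0 * w0 / (m0 - 1) + w1 * w1 / (m1 - 1))


def _tcrit(alpha: float, sides: str, df: float) -> float:
    q = 1.0 - alpha if sides == "one_sided" else 1.0 - alpha / 2.0
    return float(stats.t.ppf(q, df))


def _beta_from_ncp(ncp: float, df: float, tcrit: float, cdf_mode: str) -> float:
    # Probability of landing below the critical value under the alternative.
    # The two-sided variant neglects rejection in the wrong tail; the
    # neglected mass is below machine noise for any practically relevant ncp.
    if cdf_mode == "shifted_central_t":
        return float(stats.t.cdf(tcrit - ncp, df))
    return float(stats.nct.cdf(tcrit, df, ncp))


def _warn_if_wrong_direction(ncp: float, t: TestSpec) -> None:
    if t.sides == "one_sided" and ncp < 0.0:
        warnings.warn(
            "noncentrality is negative for a one-sided test: the hypothesized "
            "direction (case > control) opposes the specified means, and beta "
            "will exceed 1 - alpha",
            UserWarning,
            stacklevel=3,
        )


def fnr_unpaired(g0: GroupSpec, g1: GroupSpec, t: TestSpec) -> PowerResult:
    """False-negative rate of the unpaired Welch t-test.

    ``g0`` is the control arm, ``g1`` the case arm.  The model mean and
    variance of each arm's observed proportion (beta-binomial, hence
    inflated by finite cells) replace the unknown population moments in the
    noncentrality and the Satterthwaite degrees of freedom.
    """
    if t.design != "unpaired":
        raise ValueError("fnr_unpaired requires an unpaired TestSpec")
    mom0 = observed_proportion_moments(g0)
    mom1 = observed_proportion_moments(g1)
    return _fnr_from_moments(
        mom0.mean, mom0.variance, g0.m, mom1.mean, mom1.variance, g1.m, t
    )


def fnr_legacy(
    mu0: float,
    sigma0: float,
    m0: int,
    mu1: float,
    sigma1: float,
    m1: int,
    t: TestSpec,
) -> PowerResult:
    """Classical t-test power calculation ignoring finite-cell noise.

    Uses the raw between-subject variances ``sigma_i^2`` as the variance of
    the observed proportion — effectively assuming infinitely many cells
    per sample.  Always at least as optimistic as :func:`fnr_unpaired`
    (or :func:`fnr_paired` for a paired spec, where the covariance term
    ``rho sigma0 sigma1`` is likewise taken at the infinite-cell limit).
    """
    if t.design == "paired":
        if m0 != m1:
            raise ValueError("paired design requires equal group sizes")
        rho = 0.0 if t.rho is None else t.rho
        var_diff = sigma1**2 + sigma0**2 - 2.0 * rho * sigma0 * sigma1
        if var_diff <= 0.0:
            raise ValueError("variance of the paired difference is non-positive")
        df = float(m0 - 1)
        ncp = (mu1 - mu0) / math.sqrt(var_diff / m0)
        _warn_if_wrong_direction(ncp, t)
        tcrit = _tcrit(t.alpha, t.sides, df)
        beta = _beta_from_ncp(ncp, df, tcrit, t.cdf_mode)
        return PowerResult(beta=beta, ncp=ncp, df=df, tcrit=tcrit)
    return _fnr_from_moments(mu0, sigma0**2, m0, mu1, sigma1**2, m1, t)


def _fnr_from_moments(e0, v0, m0, e1, v1, m1, t: TestSpec) -> PowerResult:
    df = welch_df(v0, v1, m0, m1)
    ncp = (e1 - e0) / math.sqrt(v1 / m1 + v0 / m0)
    _warn_if_wrong_direction(ncp, t)
    tcrit = _tcrit(t.alpha, t.sides, df)
    beta = _beta_from_ncp(ncp, df, tcrit, t.cdf_mode)
    return PowerResult(beta=beta, ncp=ncp, df=df, tcrit=tcrit)


def paired_cov(g0: GroupSpec, g1: GroupSpec, rho: float) -> float:
    """Covariance of the observed proportions of a matched pair.

    By the law of total covariance, the binomial layers are conditionally
    independent given the true proportions, so the covariance is carried
    entirely by the latent beta pair:
    ``cov(p0_hat, p1_hat) = rho * sigma0 * sigma1`` (the beta variances'
    geometric mean scaled by rho).  The correlation of *observed*
    proportions is attenuated relative to rho by the factor
    ``n_i / sqrt(n_i (a_i + b_i + n_i))`` per arm, approaching rho as cell
    counts grow.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho={rho!r} must lie in [-1, 1]")
    return rho * math.sqrt(g0.beta_variance * g1.beta_variance)


def observed_correlation(g0: GroupSpec, g1: GroupSpec, rho: float) -> float:
    """Correlation of observed proportions implied by latent correlation rho."""
    s0, s1 = g0.a + g0.b, g1.a + g1.b
    att0 = g0.n / math.sqrt(g0.n * (s0 + g0.n))
    att1 = g1.n / math.sqrt(g1.n * (s1 + g1.n))
    return rho * att0 * att1


def fnr_paired(g0: GroupSpec, g1: GroupSpec, t: TestSpec) -> PowerResult:
    """False-negative rate of the paired t-test on within-subject differences.

    The variance of the paired difference is
    ``V[p1] + V[p0] - 2 cov(p0, p1)``; the noncentrality divides the mean
    difference by the standard error of the mean difference
    ``sqrt(var_diff / M)`` and the degrees of freedom are ``M - 1``.
    At ``rho = 0`` the noncentrality coincides with the unpaired one (only
    the degrees of freedom differ); positive correlation shrinks the
    difference variance and increases power.
    """
    if t.design != "paired":
        raise ValueError("fnr_paired requires a paired TestSpec")
    if g0.m != g1.m:
        raise ValueError(
            f"paired design requires equal group sizes (got m0={g0.m}, m1={g1.m})"
        )
    rho = 0.0 if t.rho is None else t.rho
    if rho < 0.0:
        warnings.warn(
            "negative rho makes the paired test less powerful than the "
            "unpaired test; negative sample correlations are usually artifacts",
            UserWarning,
            stacklevel=2,
        )
    mom0 = observed_proportion_moments(g0)
    mom1 = observed_proportion_moments(g1)
    var_diff = mom1.variance + mom0.variance - 2.0 * paired_cov(g0, g1, rho)
    if var_diff <= 0.0:
        raise ValueError(
            f"variance of the paired difference is non-positive ({var_diff:.3g}); "
            "rho is too extreme for these arms"
        )
    M = g0.m
    df = float(M - 1)
    ncp = (mom1.mean - mom0.mean) / math.sqrt(var_diff / M)
    _warn_if_wrong_direction(ncp, t)
    tcrit = _tcrit(t.alpha, t.sides, df)
    beta = _beta_from_ncp(ncp, df, tcrit, t.cdf_mode)
    return PowerResult(beta=beta, ncp=ncp, df=df, tcrit=tcrit)


def fnr(g0: GroupSpec, g1: GroupSpec, t: TestSpec) -> PowerResult:
    """Dispatch to the unpaired or paired engine, applying any SESOI shift.

    A positive ``t.sesoi`` translates the control mean toward the case mean
    by the margin before testing, so the test only detects differences
    exceeding the margin.
    """
    if t.sesoi > 0.0:
        direction = "add" if g1.mu >= g0.mu else "subtract"
        g0 = apply_sesoi(g0, t.sesoi, direction)
        t = replace(t, sesoi=0.0)
    if t.design == "paired":
        return fnr_paired(g0, g1, t)
    return fnr_unpaired(g0, g1, t)


def apply_sesoi(g0: GroupSpec, margin: float, direction: str = "add") -> GroupSpec:
    """Translate the control arm's mean by the SESOI margin.

    The shift is applied to the mean before the beta reparametrization; the
    standard deviation is unchanged.  Raises if the shifted mean leaves
    (0, 1) or violates the beta variance bound at the new mean.
    """
    if margin < 0.0:
        raise ValueError("SESOI margin must be non-negative")
    if direction not in ("add", "subtract"):
        raise ValueError(f"direction must be 'add' or 'subtract', got {direction!r}")
    if margin == 0.0:
        return g0
    mu = g0.mu + margin if direction == "add" else g0.mu - margin
    if not 0.0 < mu < 1.0:
        raise ValueError(
            f"SESOI-shifted mean {mu:.4g} leaves (0, 1) (mu0={g0.mu}, margin={margin})"
        )
    return g0.with_mean(mu)


def tost_power(
    g0: GroupSpec, g1: GroupSpec, margin: float, t: TestSpec
) -> PowerResult:
    """Power of the two one-sided tests (TOST) procedure for equivalence.

    Declares the case and control proportions equivalent when both
    one-sided tests reject: the difference is significantly above
    ``-margin`` AND significantly below ``+margin``.  The joint rejection
    probability is bounded below by ``max(0, power_lower + power_upper - 1)``
    (the conservative intersection bound), which is what this function
    returns as ``power``; ``beta`` is its complement.  Meaningful power
    requires the true absolute mean difference to be inside the margin.
    """
    if margin <= 0.0:
        raise ValueError("TOST margin must be positive")
    mom0 = observed_proportion_moments(g0)
    mom1 = observed_proportion_moments(g1)
    e0, v0, e1, v1 = mom0.mean, mom0.variance, mom1.mean, mom1.variance
    df = welch_df(v0, v1, g0.m, g1.m)
    se = math.sqrt(v1 / g1.m + v0 / g0.m)
    diff = e1 - e0
    tcrit = float(stats.t.ppf(1.0 - t.alpha, df))  # each arm tested one-sided
    # lower test: H0 diff <= -margin, reject when t computed against -margin is large
    ncp_lower = (diff + margin) / se
    power_lower = 1.0 - _beta_from_ncp(ncp_lower, df, tcrit, t.cdf_mode)
    # upper test: H0 diff >= +margin, reject when t against +margin is very negative
    ncp_upper = (margin - diff) / se
    power_upper = 1.0 - _beta_from_ncp(ncp_upper, df, tcrit, t.cdf_mode)
    power = max(0.0, power_lower + power_upper - 1.0)
    return PowerResult(beta=1.0 - power, ncp=min(ncp_lower, ncp_upper), df=df, tcrit=tcrit)
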