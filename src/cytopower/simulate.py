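"""Monte-Carlo validation of the analytic power engine.

Generates synthetic experiments from the exact generative model the
analytic engine approximates — per sample a true proportion drawn from
Beta(a, b), then a Binomial(n, p) cell count — runs the configured t-test
on each replicate, and compares the empirical fraction of non-rejections
(the empirical false-negative rate) with the closed-form prediction.

Paired experiments couple the two beta marginals through a Gaussian
copula whose correlation is calibrated numerically so the latent pair has
the requested product-moment correlation rho; the binomial thinning layer
stays conditionally independent, as the model requires.

All randomness flows from a single root seed; per-replicate substreams
are derived with ``numpy.random.SeedSequence.spawn`` so results are
bit-reproducible and stable under changes to the replicate count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .model import GroupSpec, observed_proportion_moments
from .power import TestSpec, fnr, fnr_legacy

__all__ = [
    "SimConfig",
    "SimResult",
    "draw_dataset",
    "empirical_fnr",
    "grid_validation",
    "empirical_resample_fnr",
    "copula_correlation_for_rho",
]


@dataclass(frozen=True)
class SimConfig:
    """One Monte-Carlo experiment: two arms, a test, replicates, a seed."""

    g0: GroupSpec
    g1: GroupSpec
    test: TestSpec
    replicates: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class SimResult:
    """Empirical type-II error next to the analytic prediction.

    ``abs_rel_diff`` is |empirical - analytic| / empirical; it is NaN when
    the empirical rate is exactly zero (``zero_empirical`` flags that).
    """

    empirical_fnr: float
    replicates: int
    analytic_fnr: float
    abs_rel_diff: float
    zero_empirical: bool = False


# ---------------------------------------------------------------------------
# copula calibration

def _latent_corr(rho_z: float, g0: GroupSpec, g1: GroupSpec, nodes: int = 48) -> float:
    """Product-moment correlation of the beta pair induced by a Gaussian
    copula with normal correlation ``rho_z``, by Gauss-Hermite quadrature."""
    x, w = np.polynomial.hermite_e.hermegauss(nodes)
    w = w / math.sqrt(2.0 * math.pi)
    # bivariate standard normal via z1 = rho_z*z0 + sqrt(1-rho_z^2)*e
    z0 = x[:, None]
    e = x[None, :]
    z1 = rho_z * z0 + math.sqrt(max(0.0, 1.0 - rho_z * rho_z)) * e
    p0 = stats.beta.ppf(stats.norm.cdf(z0), g0.a, g0.b)
    p1 = stats.beta.ppf(stats.norm.cdf(z1), g1.a, g1.b)
    ww = w[:, None] * w[None, :]
    m0, m1 = g0.mu, g1.mu
    cov = float(np.sum(ww * (p0 - m0) * (p1 - m1)))
    return cov / math.sqrt(g0.beta_variance * g1.beta_variance)


def copula_correlation_for_rho(g0: GroupSpec, g1: GroupSpec, rho: float) -> float:
    """Gaussian-copula correlation giving the beta pair correlation ``rho``.

    The map rho_z -> corr(p0, p1) is continuous and strictly increasing
    with corr(0) = 0, so a bracketed root search suffices.  Exact at the
    endpoints and at zero.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    if rho == 0.0:
        return 0.0
    if abs(rho) >= 1.0 - 1e-12:
        return math.copysign(1.0, rho)
    f = lambda rz: _latent_corr(rz, g0, g1) - rho
    lo, hi = (0.0, 1.0 - 1e-9) if rho > 0 else (-1.0 + 1e-9, 0.0)
    return float(brentq(f, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# dataset generation

def draw_dataset(
    c: SimConfig, rng: np.random.Generator | None = None, size: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Observed proportions for ``size`` replicate experiments.

    Returns arrays of shape ``(size, m0)`` and ``(size, m1)``.  Unpaired:
    independent Beta then Binomial per sample.  Paired: latent beta pairs
    through the calibrated Gaussian copula, then independent binomial
    thinning per condition.
    """
    if rng is None:
        rng = np.random.default_rng(c.seed)
    g0, g1 = c.g0, c.g1
    if c.test.design == "paired":
        rho = 0.0 if c.test.rho is None else c.test.rho
        rho_z = copula_correlation_for_rho(g0, g1, rho)
        z0 = rng.standard_normal((size, g0.m))
        e = rng.standard_normal((size, g0.m))
        z1 = rho_z * z0 + math.sqrt(max(0.0, 1.0 - rho_z * rho_z)) * e
        p0 = stats.beta.ppf(stats.norm.cdf(z0), g0.a, g0.b)
        p1 = stats.beta.ppf(stats.norm.cdf(z1), g1.a, g1.b)
    else:
        p0 = rng.beta(g0.a, g0.b, (size, g0.m))
        p1 = rng.beta(g1.a, g1.b, (size, g1.m))
    x0 = rng.binomial(g0.n, p0) / g0.n
    x1 = rng.binomial(g1.n, p1) / g1.n
    return x0, x1


def draw_latent_pairs(
    c: SimConfig, rng: np.random.Generator, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Latent (pre-thinning) beta proportion pairs for a paired config."""
    rho = 0.0 if c.test.rho is None else c.test.rho
    rho_z = copula_correlation_for_rho(c.g0, c.g1, rho)
    z0 = rng.standard_normal(size)
    e = rng.standard_normal(size)
    z1 = rho_z * z0 + math.sqrt(max(0.0, 1.0 - rho_z * rho_z)) * e
    p0 = stats.beta.ppf(stats.norm.cdf(z0), c.g0.a, c.g0.b)
    p1 = stats.beta.ppf(stats.norm.cdf(z1), c.g1.a, c.g1.b)
    return p0, p1


# ---------------------------------------------------------------------------
# vectorized tests

def _welch_reject(x0: np.ndarray, x1: np.ndarray, alpha: float, sides: str) -> np.ndarray:
    """Per-replicate Welch t-test rejections (one-sided: case > control)."""
    m0, m1 = x0.shape[1], x1.shape[1]
    mean0, mean1 = x0.mean(axis=1), x1.mean(axis=1)
    v0, v1 = x0.var(axis=1, ddof=1), x1.var(axis=1, ddof=1)
    w0, w1 = v0 / m0, v1 / m1
    se = np.sqrt(w0 + w1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = (mean1 - mean0) / se
        df = (w0 + w1) ** 2 / (w0**2 / (m0 - 1) + w1**2 / (m1 - 1))
    # degenerate replicates (both sample variances zero) cannot reject
    ok = np.isfinite(tval) & np.isfinite(df)
    reject = np.zeros(x0.shape[0], dtype=bool)
    if sides == "one_sided":
        crit = stats.t.ppf(1.0 - alpha, df[ok])
        reject[ok] = tval[ok] > crit
    else:
        crit = stats.t.ppf(1.0 - alpha / 2.0, df[ok])
        reject[ok] = np.abs(tval[ok]) > crit
    return reject


def _paired_reject(x0: np.ndarray, x1: np.ndarray, alpha: float, sides: str) -> np.ndarray:
    """Per-replicate paired t-test rejections on within-pair differences."""
    d = x1 - x0
    M = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = mean / (sd / math.sqrt(M))
    ok = np.isfinite(tval)
    reject = np.zeros(d.shape[0], dtype=bool)
    crit = stats.t.ppf(1.0 - (alpha if sides == "one_sided" else alpha / 2.0), M - 1)
    if sides == "one_sided":
        reject[ok] = tval[ok] > crit
    else:
        reject[ok] = np.abs(tval[ok]) > crit
    return reject


def empirical_fnr(c: SimConfig) -> SimResult:
    """Empirical false-negative rate over ``c.replicates`` experiments.

    Each replicate draws a fresh dataset from the beta-binomial model and
    applies the configured test (Welch unpaired or paired t) at level
    alpha; the empirical rate is the fraction of non-rejections, reported
    next to the engine's analytic prediction.
    """
    root = np.random.SeedSequence(c.seed)
    rng = np.random.default_rng(root)
    x0, x1 = draw_dataset(c, rng, size=c.replicates)
    if c.test.design == "paired":
        reject = _paired_reject(x0, x1, c.test.alpha, c.test.sides)
    else:
        reject = _welch_reject(x0, x1, c.test.alpha, c.test.sides)
    emp = float(1.0 - reject.mean())
    analytic = fnr(c.g0, c.g1, c.test).beta
    if emp == 0.0:
        return SimResult(0.0, c.replicates, analytic, float("nan"), True)
    return SimResult(emp, c.replicates, analytic, abs(emp - analytic) / emp, False)


def grid_validation(
    m_pairs: list[tuple[int, int]],
    g0_base: GroupSpec,
    g1_base: GroupSpec,
    test: TestSpec,
    replicates: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Validate the analytic engine against simulation over a size grid.

    For each (m0, m1) pair: simulate ``replicates`` datasets, measure the
    empirical false-negative rate, and record both the finite-cell
    analytic prediction and the legacy (infinite-cell) one.  Returns the
    grid-mean absolute relative error of each prediction (cells with an
    empirical rate of exactly zero are excluded from the means) and the
    per-cell table.
    """
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(m_pairs))
    rows = []
    for (m0, m1), ss in zip(m_pairs, children):
        g0, g1 = g0_base.with_m(m0), g1_base.with_m(m1)
        cfg = SimConfig(g0, g1, test, replicates, 0)
        rng = np.random.default_rng(ss)
        x0, x1 = draw_dataset(cfg, rng, size=replicates)
        if test.design == "paired":
            reject = _paired_reject(x0, x1, test.alpha, test.sides)
        else:
            reject = _welch_reject(x0, x1, test.alpha, test.sides)
        emp = float(1.0 - reject.mean())
        sensei = fnr(g0, g1, test).beta
        legacy = fnr_legacy(g0.mu, g0.sigma, m0, g1.mu, g1.sigma, m1, test).beta
        rows.append(
            dict(m0=m0, m1=m1, empirical_fnr=emp, sensei_fnr=sensei,
                 legacy_fnr=legacy, replicates=replicates, seed=seed)
        )
    table = pd.DataFrame(rows)
    usable = table["empirical_fnr"] > 0.0
    emp = table.loc[usable, "empirical_fnr"]
    err_model = float((np.abs(table.loc[usable, "sensei_fnr"] - emp) / emp).mean())
    err_legacy = float((np.abs(table.loc[usable, "legacy_fnr"] - emp) / emp).mean())
    table.attrs["excluded_zero_cells"] = int((~usable).sum())
    return err_model, err_legacy, table


def empirical_resample_fnr(
    proportions0,
    proportions1,
    m0: int,
    m1: int,
    n0: int,
    n1: int,
    alpha: float = 0.05,
    repeats: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical power validation by resampling pilot proportions.

    Each repeat draws ``m_i`` pilot proportions per group with
    replacement, simulates the single-cell assay by binomial thinning
    through ``Binomial(n_i, p)``, and applies a one-sided unpaired Welch
    t-test (case > control) at level alpha.  Returns the fraction of
    non-rejections — the empirical false-negative rate under the pilot
    data's own empirical distribution.
    """
    p0 = np.asarray(proportions0, dtype=float)
    p1 = np.asarray(proportions1, dtype=float)
    if p0.size == 0 or p1.size == 0:
        raise ValueError("pilot proportion vectors must be nonempty")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws0 = rng.choice(p0, size=(repeats, m0), replace=True)
    draws1 = rng.choice(p1, size=(repeats, m1), replace=True)
    x0 = rng.binomial(n0, draws0) / n0
    x1 = rng.binomial(n1, draws1) / n1
    reject = _welch_reject(x0, x1, alpha, "one_sided")
    return float(1.0 - reject.mean())
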