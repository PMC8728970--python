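"""Estimate design inputs (mean, SD, correlation) from pilot data.

A small pilot study of per-sample cell-type proportions can supply the
mean, between-subject standard deviation and (for paired designs) the
between-condition correlation that the power engine needs, together with
confidence intervals that indicate how trustworthy those priors are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PriorSummary",
    "summarize_group",
    "correlation_with_ci",
    "read_pilot_table",
    "summarize_pilot",
]


@dataclass(frozen=True)
class PriorSummary:
    """Point estimates with confidence limits for one pilot group.

    The mean limits are clipped to [0, 1] (a proportion cannot leave the
    unit interval even when the t interval does); correlation limits, when
    present, lie in [-1, 1] by construction of the Fisher-z transform.
    """

    mean: float
    mean_low: float
    mean_high: float
    sd: float
    sd_low: float
    sd_high: float
    n_samples: int
    conf_level: float
    correlation: float | None = None
    corr_low: float | None = None
    corr_high: float | None = None


def summarize_group(
    proportions: Sequence[float], conf_level: float = 0.95
) -> PriorSummary:
    """Sample mean and SD of pilot proportions with textbook intervals.

    The mean interval is ``p_bar ± t_{1-alpha/2, n-1} s / sqrt(n)`` with
    limits clipped to [0, 1]; the SD interval comes from the chi-square
    quantiles of ``(n-1) s^2 / sigma^2``.  A degenerate sample (all values
    identical) yields a point interval rather than an error.
    """
    p = np.asarray(proportions, dtype=float)
    if p.size < 2:
        raise ValueError("need at least 2 pilot proportions")
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("pilot proportions must lie in [0, 1]")
    if not 0.0 < conf_level < 1.0:
        raise ValueError("conf_level must lie in (0, 1)")
    n = p.size
    mean = float(p.mean())
    s = float(p.std(ddof=1))
    alpha = 1.0 - conf_level
    if s == 0.0:
        return PriorSummary(mean, mean, mean, 0.0, 0.0, 0.0, n, conf_level)
    tq = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    half = tq * s / math.sqrt(n)
    mean_low = min(max(mean - half, 0.0), 1.0)
    mean_high = min(max(mean + half, 0.0), 1.0)
    chi_hi = stats.chi2.ppf(1.0 - alpha / 2.0, n - 1)
    chi_lo = stats.chi2.ppf(alpha / 2.0, n - 1)
    sd_low = math.sqrt((n - 1) * s * s / chi_hi)
    sd_high = math.sqrt((n - 1) * s * s / chi_lo)
    return PriorSummary(mean, mean_low, mean_high, s, sd_low, sd_high, n, conf_level)


def correlation_with_ci(
    pairs: Sequence[tuple[float, float]], conf_level: float = 0.95
) -> tuple[float, float, float]:
    """Pearson correlation of matched pilot pairs with a Fisher-z interval.

    Limits are ``tanh(arctanh r ± z_{1-alpha/2} / sqrt(n - 3))``; at least
    4 pairs are required for the Fisher-z denominator to be positive.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (p0, p1) tuples")
    n = arr.shape[0]
    if n < 4:
        raise ValueError("need at least 4 matched pairs for a correlation interval")
    x, y = arr[:, 0], arr[:, 1]
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("correlation undefined: a margin has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    z = stats.norm.ppf(1.0 - (1.0 - conf_level) / 2.0)
    half = z / math.sqrt(n - 3)
    lo = math.tanh(math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15)) - half)
    hi = math.tanh(math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15)) + half)
    return r, lo, hi


_GROUP_ALIASES = {"0": 0, "control": 0, "1": 1, "case": 1}


def read_pilot_table(path: str | Path) -> pd.DataFrame:
    """Read a pilot CSV with columns sample_id, group, proportion.

    ``group`` may be 0/1 or control/case.  An optional ``subject_id``
    column links matched pairs for paired designs.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "group", "proportion"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pilot table missing columns: {sorted(missing)}")
    df = df.copy()
    df["group"] = [
        _GROUP_ALIASES.get(str(g).strip().lower()) for g in df["group"]
    ]
    if df["group"].isna().any():
        raise ValueError("group column must contain 0/1 or control/case")
    props = df["proportion"].astype(float)
    if ((props < 0) | (props > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    df["proportion"] = props
    return df


def summarize_pilot(
    df: pd.DataFrame, conf_level: float = 0.95
) -> dict[int, PriorSummary]:
    """Per-group prior summaries from a pilot table.

    When a ``subject_id`` column is present and both conditions are
    observed for >= 4 subjects, the between-condition correlation and its
    Fisher-z interval are attached to both group summaries.
    """
    out: dict[int, PriorSummary] = {}
    for grp, sub in df.groupby("group"):
        out[int(grp)] = summarize_group(sub["proportion"].to_list(), conf_level)
    if "subject_id" in df.columns and set(out) == {0, 1}:
        wide = df.pivot_table(
            index="subject_id", columns="group", values="proportion", aggfunc="first"
        ).dropna()
        if len(wide) >= 4:
            r, lo, hi = correlation_with_ci(
                list(zip(wide[0], wide[1])), conf_level
            )
            out = {
                g: PriorSummary(
                    s.mean, s.mean_low, s.mean_high, s.sd, s.sd_low, s.sd_high,
                    s.n_samples, s.conf_level, r, lo, hi,
                )
                for g, s in out.items()
            }
    return out
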