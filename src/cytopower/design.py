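"""Sample-size search and false-negative-rate tabulation.

Given the per-arm model parameters and a test configuration, these
helpers sweep sample-size grids (the classic design table: control sizes
down the rows, case sizes across the columns, type-II error in the cells),
find the smallest equal group size that reaches a power target, and trace
how that minimal size trades off against the number of cells per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import GroupSpec
from .power import TestSpec, fnr, fnr_legacy

__all__ = ["FnrTable", "fnr_table", "min_sample_size", "min_sample_size_unequal", "cells_tradeoff"]

#: largest group size considered before a design is declared infeasible
DEFAULT_M_MAX = 200


@dataclass(frozen=True)
class FnrTable:
    """Type-II-error table over a grid of sample sizes.

    ``values`` is indexed by control size (rows) and case size (columns);
    for a paired design only the diagonal is meaningful and the table is
    one-dimensional in the common size M.  Cells are non-increasing along
    both axes: adding samples never hurts power.
    """

    values: pd.DataFrame
    g0: GroupSpec
    g1: GroupSpec
    test: TestSpec
    paired: bool = field(default=False)

    def to_csv(self, path: str | Path) -> None:
        """Write the table with 3-decimal cells (design-report precision)."""
        out = self.values.round(3)
        out.to_csv(path, float_format="%.3f")

    def to_json(self, path: str | Path) -> None:
        """Write full-precision cells plus the complete parameter metadata."""
        import json

        payload = {
            "rows_control_m": [int(i) for i in self.values.index],
            "cols_case_m": [int(c) for c in self.values.columns],
            "beta": self.values.to_numpy().tolist(),
            "paired": self.paired,
            "g0": {"n": self.g0.n, "mu": self.g0.mu, "sigma": self.g0.sigma},
            "g1": {"n": self.g1.n, "mu": self.g1.mu, "sigma": self.g1.sigma},
            "test": {
                "alpha": self.test.alpha,
                "sides": self.test.sides,
                "design": self.test.design,
                "rho": self.test.rho,
                "sesoi": self.test.sesoi,
                "cdf_mode": self.test.cdf_mode,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def fnr_table(
    g0_base: GroupSpec,
    g1_base: GroupSpec,
    m0_range: Sequence[int],
    m1_range: Sequence[int],
    t: TestSpec,
) -> FnrTable:
    """Tabulate the false-negative rate over a sample-size grid.

    For a paired design the two ranges must coincide and only the diagonal
    (equal sizes) is populated; off-diagonal cells are NaN.
    """
    m0s = [int(m) for m in m0_range]
    m1s = [int(m) for m in m1_range]
    if any(m < 2 for m in m0s + m1s):
        raise ValueError("sample sizes must be integers >= 2")
    paired = t.design == "paired"
    if paired and m0s != m1s:
        raise ValueError("paired design requires identical control/case size ranges")
    cells = np.full((len(m0s), len(m1s)), np.nan)
    for i, m0 in enumerate(m0s):
        for j, m1 in enumerate(m1s):
            if paired and m0 != m1:
                continue
            cells[i, j] = fnr(g0_base.with_m(m0), g1_base.with_m(m1), t).beta
    df = pd.DataFrame(cells, index=pd.Index(m0s, name="control_m"),
                      columns=pd.Index(m1s, name="case_m"))
    return FnrTable(values=df, g0=g0_base, g1=g1_base, test=t, paired=paired)


def min_sample_size(
    g0: GroupSpec,
    g1: GroupSpec,
    t: TestSpec,
    power_target: float,
    m_max: int = DEFAULT_M_MAX,
) -> int | None:
    """Smallest equal group size M in [2, m_max] reaching the power target.

    Linear upward scan (beta is monotone in M, but a linear scan over at
    most a couple hundred candidates is fast and immune to floating-point
    plateaus).  Returns None when no feasible size exists below ``m_max``.
    """
    if not 0.0 < power_target < 1.0:
        raise ValueError("power_target must lie in (0, 1)")
    if m_max < 2:
        raise ValueError("m_max must be >= 2")
    for M in range(2, m_max + 1):
        res = fnr(g0.with_m(M), g1.with_m(M), t)
        if res.power >= power_target:
            return M
    return None


def min_sample_size_unequal(
    g0: GroupSpec,
    g1: GroupSpec,
    t: TestSpec,
    power_target: float,
    fixed_m0: int,
    m_max: int = DEFAULT_M_MAX,
) -> int | None:
    """Smallest case size m1 meeting the target with the control size fixed.

    Group sizes are allowed to differ between arms; this scans m1 upward
    holding m0 at ``fixed_m0``.
    """
    if not 0.0 < power_target < 1.0:
        raise ValueError("power_target must lie in (0, 1)")
    if fixed_m0 < 2:
        raise ValueError("fixed_m0 must be >= 2")
    if t.design == "paired":
        raise ValueError("unequal sizes are not possible in a paired design")
    g0 = g0.with_m(fixed_m0)
    for m1 in range(2, m_max + 1):
        if fnr(g0, g1.with_m(m1), t).power >= power_target:
            return m1
    return None


def cells_tradeoff(
    g0: GroupSpec,
    g1: GroupSpec,
    t: TestSpec,
    power_target: float,
    n_values: Sequence[int | None],
    m_max: int = DEFAULT_M_MAX,
) -> dict[int | None, int | None]:
    """Minimal equal group size per cells-per-sample value.

    ``None`` in ``n_values`` denotes the infinite-cell (legacy)
    calculation.  Because the observed-proportion variance shrinks as the
    cell count grows, the minimal sample size is non-increasing in n, with
    the legacy value as its floor.
    """
    out: dict[int | None, int | None] = {}
    for n in n_values:
        if n is None:
            out[n] = _min_m_legacy(g0, g1, t, power_target, m_max)
        else:
            out[n] = min_sample_size(g0.with_n(int(n)), g1.with_n(int(n)), t,
                                     power_target, m_max)
    return out


def _min_m_legacy(g0, g1, t, power_target, m_max):
    for M in range(2, m_max + 1):
        res = fnr_legacy(g0.mu, g0.sigma, M, g1.mu, g1.sigma, M, t)
        if res.power >= power_target:
            return M
    return None
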