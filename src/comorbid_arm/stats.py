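"""Prevalence tables and χ² tests with Bonferroni correction."""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["PrevalenceRow", "ChiSquareResult", "round_half_up",
           "prevalence_table", "chi2_test"]


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, as in the reported tables."""
    x = float(x)
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrevalenceRow:
    stratum_label: str
    n_total: int
    n_condition: int
    pct: float  # 100 * n_condition / n_total, rounded half-up to 1 dp


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_raw: float
    p_adj: float
    m: int


def prevalence_table(profiles: pd.DataFrame, stratifier: str, condition: str):
    """Prevalence of a boolean condition within each stratum plus Total.

    One :class:`PrevalenceRow` per observed stratum value (empty strata are
    simply absent) followed by a Total row; condition counts across strata
    sum to the Total row's count.
    """
    if len(profiles) == 0:
        raise ValueError("empty cohort: nothing to tabulate")
    for col in (stratifier, condition):
        if col not in profiles.columns:
            raise KeyError(f"{col!r} is not a profile field")
    rows = []
    grouped = profiles.groupby(stratifier, sort=True, observed=True)[condition]
    for stratum, vals in grouped:
        n_total = int(vals.size)
        n_cond = int(vals.sum())
        rows.append(
            PrevalenceRow(str(stratum), n_total, n_cond,
                          round_half_up(100.0 * n_cond / n_total, 1))
        )
    n_total = int(len(profiles))
    n_cond = int(profiles[condition].sum())
    rows.append(
        PrevalenceRow("Total", n_total, n_cond,
                      round_half_up(100.0 * n_cond / n_total, 1))
    )
    return rows


def prevalence_frame(profiles: pd.DataFrame, stratifier: str, condition: str):
    rows = prevalence_table(profiles, stratifier, condition)
    return pd.DataFrame(
        [(r.stratum_label, r.n_total, r.n_condition, r.pct) for r in rows],
        columns=[stratifier, "n_total", f"n_{condition}", "pct"],
    )


def chi2_test(table, m: int = 1) -> ChiSquareResult:
    """Pearson χ² test of independence on a 2×K table, Bonferroni-adjusted.

    No continuity correction (plain Pearson, appropriate for registry-scale
    counts). ``m`` is the size of the test family sharing the correction;
    p_adj = min(1, m * p_raw).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.min() < 0:
        raise ValueError("contingency table must be 2-D with non-negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    if m < 1:
        raise ValueError("family size m must be >= 1")
    stat, p_raw, df, _ = sps.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        p_raw=float(p_raw),
        p_adj=min(1.0, m * float(p_raw)),
        m=m,
    )
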