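"""Descriptive stage: elderly filtering, currency conversion, grouped summaries.

Mirrors the survey paper's descriptive table: per category level, the
household count, its percent share and the mean/SD of out-of-pocket
pharmaceutical expenditure (zeros included, sample SD with the n-1
denominator).  Raw outputs are unformatted floats in USD; ``format_table1``
renders a fixed 2-dp report layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CATEGORY_LEVELS
from .errors import DataError

RIALS_PER_USD = 129_000.0

__all__ = [
    "GroupSummary",
    "convert_rial_to_usd",
    "filter_elderly_households",
    "group_summary",
    "zero_share",
    "oop_extremes",
    "summary_frame",
    "format_table1",
]


@dataclass
class GroupSummary:
    """One row of the descriptive table: a category level of one variable."""

    variable: str
    level: str
    frequency: int
    percent: float
    mean_oop: float
    sd_oop: float


def convert_rial_to_usd(amount_rials):
    """Convert Rial amounts to USD at the survey's 129,000 Rials/USD rate."""
    arr = np.asarray(amount_rials, dtype=float)
    if np.any(arr < 0):
        raise DataError("monetary amounts must be non-negative")
    out = arr / RIALS_PER_USD
    return float(out) if out.ndim == 0 else out


def filter_elderly_households(table: pd.DataFrame, age_threshold: int = 65) -> pd.DataFrame:
    """Keep households with at least one member aged ``age_threshold`` or more.

    The table must carry either a ``max_member_age`` column or a boolean
    ``has_elderly`` flag (precomputed upstream from the member roster).
    """
    if "max_member_age" in table.columns:
        mask = table["max_member_age"] >= age_threshold
    elif "has_elderly" in table.columns:
        mask = table["has_elderly"].astype(bool)
    else:
        raise DataError(
            "table carries neither 'max_member_age' nor 'has_elderly'; "
            "cannot identify elderly households"
        )
    return table.loc[mask].reset_index(drop=True)


def group_summary(table: pd.DataFrame, variable: str, include_zeros: bool = True) -> list[GroupSummary]:
    """Count/percent/mean/SD of OOPPE per level of one categorical variable.

    Percent is 100 * count / n over the whole table.  Mean and SD are over
    all households in the level (zeros included) by default; with
    ``include_zeros=False`` they cover spenders only, while counts and
    percents still cover everyone.
    """
    if len(table) == 0:
        raise DataError("cannot summarize an empty table")
    if variable not in CATEGORY_LEVELS:
        raise DataError(f"{variable!r} is not a categorical household field")
    n = len(table)
    out = []
    for level in CATEGORY_LEVELS[variable]:
        sub = table.loc[table[variable].astype(str) == level, "oop_pharma"]
        vals = sub if include_zeros else sub[sub > 0]
        count = int(len(sub))
        mean = float(vals.mean()) if len(vals) else float("nan")
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else (0.0 if len(vals) == 1 else float("nan"))
        out.append(GroupSummary(
            variable=variable, level=level, frequency=count,
            percent=100.0 * count / n, mean_oop=mean, sd_oop=sd,
        ))
    return out


def zero_share(table: pd.DataFrame) -> dict:
    """Exact count and share of zero-OOPPE households."""
    y = table["oop_pharma"].to_numpy(dtype=float)
    n_zero = int(np.sum(y == 0))
    n_total = int(y.size)
    return {"n_zero": n_zero, "n_total": n_total, "share": n_zero / n_total if n_total else float("nan")}


def oop_extremes(table: pd.DataFrame, include_zeros_in_mean: bool = True) -> dict:
    """Minimum positive, maximum and mean OOPPE.

    The minimum is taken over positive values (a zero minimum is always
    trivially attained when non-spenders exist); the mean includes zeros by
    default, matching a per-household average.
    """
    if len(table) == 0:
        raise DataError("cannot summarize an empty table")
    y = table["oop_pharma"].to_numpy(dtype=float)
    pos = y[y > 0]
    return {
        "min_positive": float(pos.min()) if pos.size else float("nan"),
        "max": float(y.max()),
        "mean": float(y.mean() if include_zeros_in_mean else (pos.mean() if pos.size else float("nan"))),
    }


def summary_frame(table: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Stack :func:`group_summary` over several variables into a DataFrame."""
    variables = variables if variables is not None else list(CATEGORY_LEVELS)
    rows = [vars(g) for v in variables for g in group_summary(table, v)]
    return pd.DataFrame(rows)


def format_table1(table: pd.DataFrame, variables=None) -> str:
    """Human-readable descriptive report (2-dp, half-even rounding)."""
    frame = summary_frame(table, variables)
    lines = [f"{'Variable':<20}{'Level':<14}{'Freq':>7}{'Percent':>9}{'Mean':>11}{'SD':>11}"]
    for _, r in frame.iterrows():
        lines.append(
            f"{r['variable']:<20}{r['level']:<14}{r['frequency']:>7d}"
            f"{r['percent']:>9.2f}{r['mean_oop']:>11.2f}{r['sd_oop']:>11.2f}"
        )
    zs = zero_share(table)
    ext = oop_extremes(table)
    lines.append("")
    lines.append(
        f"zero OOPPE: {zs['n_zero']} of {zs['n_total']} households "
        f"({100 * zs['share']:.2f}%)"
    )
    lines.append(
        f"OOPPE (USD): min positive {ext['min_positive']:.3f}, "
        f"max {ext['max']:.3f}, mean {ext['mean']:.3f}"
    )
    return "\n".join(lines)
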