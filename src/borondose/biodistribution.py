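"""Boron biodistribution summaries: tissue concentrations, ratios, retention.

Tissue tables carry replicate-animal boron concentrations (ug B/g) per
carrier x time x tissue; cellular tables carry intracellular
concentrations (ug B/10^9 cells) over an exposure phase and a washout
phase.  Summaries follow the conventions of published biodistribution
tables: arithmetic mean +/- sample SD per cell, tumor-to-brain (T/Br)
and tumor-to-blood (T/Bl) ratios computed as ratios of means, and
washout retention expressed as a percentage of the end-of-exposure
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .errors import InputValidationError, InsufficientDataError, UndefinedResultError

__all__ = [
    "summarize_tissue",
    "tissue_ratios",
    "retention_rate",
    "compare_uptake",
    "TTestResult",
]

TISSUE_COLUMNS = ["carrier", "time_h", "tissue", "animal_id", "ug_b_per_g"]
UPTAKE_COLUMNS = ["cell_line", "carrier", "phase", "time_h", "ug_b_per_1e9_cells"]


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputValidationError(f"table is missing columns {missing}")


def summarize_tissue(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD boron concentration per (carrier, time, tissue).

    SD uses the n-1 denominator; single-animal cells report SD as
    missing (NaN), not zero, to keep "no replication" distinguishable
    from "no spread".
    """
    _require_columns(table, TISSUE_COLUMNS)
    if (table["ug_b_per_g"] < 0).any():
        raise InputValidationError("boron concentrations must be >= 0")
    g = table.groupby(["carrier", "time_h", "tissue"])["ug_b_per_g"]
    out = g.agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else np.nan)
    return out.reset_index()


def tissue_ratios(summary: pd.DataFrame, tumor: str = "tumor", brain: str = "brain",
                  blood: str = "blood") -> pd.DataFrame:
    """Tumor-to-brain and tumor-to-blood ratios of mean concentrations.

    Takes the output of :func:`summarize_tissue`; returns one row per
    (carrier, time) with unrounded ratios and one-decimal half-up
    rounded display values.  A zero denominator yields NaN with an
    ``undefined`` marker rather than an error, matching the blank-cell
    convention of report tables.
    """
    _require_columns(summary, ["carrier", "time_h", "tissue", "mean"])
    wide = summary.pivot_table(index=["carrier", "time_h"], columns="tissue", values="mean")
    rows = []
    for (carrier, time_h), r in wide.iterrows():
        row = {"carrier": carrier, "time_h": time_h}
        for name, denom_tissue in (("t_br", brain), ("t_bl", blood)):
            num = r.get(tumor, np.nan)
            den = r.get(denom_tissue, np.nan)
            if not np.isfinite(num) or not np.isfinite(den) or den == 0:
                row[name] = np.nan
                row[f"{name}_rounded"] = np.nan
                row[f"{name}_undefined"] = True
            else:
                row[name] = num / den
                row[f"{name}_rounded"] = round_half_up(num / den, 1)
                row[f"{name}_undefined"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def retention_rate(uptake: pd.DataFrame, washout_time_h: float, cell_line: Optional[str] = None,
                   carrier: Optional[str] = None, baseline_time_h: float = 24.0) -> float:
    """Percent of cellular boron retained after a washout interval.

    100 x mean concentration (washout phase, ``washout_time_h``) / mean
    concentration (exposure phase, ``baseline_time_h``).  A washout time
    of 0 is the baseline itself, i.e. 100% by definition.
    """
    _require_columns(uptake, UPTAKE_COLUMNS)
    df = uptake
    if cell_line is not None:
        df = df[df["cell_line"] == cell_line]
    if carrier is not None:
        df = df[df["carrier"] == carrier]
    base = df[(df["phase"] == "exposure") & (df["time_h"] == baseline_time_h)]
    if base.empty:
        raise InputValidationError(
            f"no exposure-phase baseline at {baseline_time_h} h for this cell line/carrier"
        )
    baseline = base["ug_b_per_1e9_cells"].mean()
    if baseline == 0:
        raise UndefinedResultError("baseline concentration is zero; retention undefined")
    if washout_time_h == 0:
        return 100.0
    washed = df[(df["phase"] == "washout") & (df["time_h"] == washout_time_h)]
    if washed.empty:
        raise InputValidationError(f"no washout measurement at {washout_time_h} h")
    return 100.0 * washed["ug_b_per_1e9_cells"].mean() / baseline


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: float
    significant: bool
    equal_var: bool


def compare_uptake(group_a, group_b, equal_var: bool = True, alpha: float = 0.05) -> TTestResult:
    """Two-sample t-test on boron concentrations of two groups.

    Pooled-variance Student's t by default; ``equal_var=False`` switches
    to Welch's correction.  Two-sided p, flagged significant at
    ``alpha``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2 for a t-test")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = res.df if hasattr(res, "df") else a.size + b.size - 2
    return TTestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        df=float(df),
        significant=bool(res.pvalue < alpha),
        equal_var=equal_var,
    )
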