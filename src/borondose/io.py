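"""CSV schema validation and publication-style report assembly.

Input tables are plain UTF-8 CSV with a header row and "." decimals;
units are encoded in column names (``ug_b_per_g``, ``dose_gy``, ...).
``validate_table`` parses a file against a named schema and either
returns the typed frame or raises :class:`~borondose.errors.SchemaError`
carrying a line-numbered report of every violated constraint.
``build_report`` renders module results as report tables: one-decimal
half-up display values next to full-precision companions, with blank
cells wherever a biological-effectiveness factor is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import SchemaError

__all__ = ["validate_table", "build_report", "SCHEMAS"]


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    dtype: str  # "str" | "float" | "int"
    check: Optional[Callable[[pd.Series], pd.Series]] = None  # mask of BAD rows
    message: str = ""


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: Tuple[ColumnSpec, ...]
    unique_key: Optional[Tuple[str, ...]] = None


def _nonneg(s: pd.Series) -> pd.Series:
    return s < 0


def _positive(s: pd.Series) -> pd.Series:
    return s <= 0


def _binary(s: pd.Series) -> pd.Series:
    return ~s.isin([0, 1])


SCHEMAS: Dict[str, TableSchema] = {
    "colony_assay": TableSchema(
        "colony_assay",
        (
            ColumnSpec("group", "str"),
            ColumnSpec("dose_gy", "float", _nonneg, "dose must be >= 0"),
            ColumnSpec("cells_seeded", "int", _positive, "cells seeded must be > 0"),
            ColumnSpec("dish_id", "str"),
            ColumnSpec("colonies", "int", _nonneg, "colony count must be >= 0"),
        ),
        unique_key=("group", "dose_gy", "dish_id"),
    ),
    "tissue_boron": TableSchema(
        "tissue_boron",
        (
            ColumnSpec("carrier", "str"),
            ColumnSpec("time_h", "float", _nonneg, "time must be >= 0"),
            ColumnSpec("tissue", "str"),
            ColumnSpec("animal_id", "str"),
            ColumnSpec("ug_b_per_g", "float", _nonneg, "concentration must be >= 0"),
        ),
        unique_key=("carrier", "time_h", "tissue", "animal_id"),
    ),
    "cellular_uptake": TableSchema(
        "cellular_uptake",
        (
            ColumnSpec("cell_line", "str"),
            ColumnSpec("carrier", "str"),
            ColumnSpec("phase", "str", lambda s: ~s.isin(["exposure", "washout"]),
                       "phase must be 'exposure' or 'washout'"),
            ColumnSpec("time_h", "float", _nonneg, "time must be >= 0"),
            ColumnSpec("ug_b_per_1e9_cells", "float", _nonneg, "concentration must be >= 0"),
        ),
    ),
    "survival": TableSchema(
        "survival",
        (
            ColumnSpec("group", "str"),
            ColumnSpec("animal_id", "str"),
            ColumnSpec("days", "float", _positive, "survival time must be > 0"),
            ColumnSpec("event", "int", _binary, "event flag must be 0 or 1"),
        ),
        unique_key=("group", "animal_id"),
    ),
}


def validate_table(path, schema_name: str) -> pd.DataFrame:
    """Parse and validate a CSV against a named schema.

    Returns the typed DataFrame on success.  On failure raises
    :class:`SchemaError` whose ``errors`` attribute lists
    ``(line_number, column, message)`` tuples; line numbers count from
    the top of the file (header = line 1).
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"could not parse {path}: {exc}") from exc

    errors: List[Tuple[int, str, str]] = []
    missing = [c.name for c in schema.columns if c.name not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}", [(1, c, "column missing") for c in missing])

    for col in schema.columns:
        series = df[col.name]
        if col.dtype in ("float", "int"):
            coerced = pd.to_numeric(series, errors="coerce")
            bad_type = coerced.isna() & series.notna()
            for idx in df.index[bad_type]:
                errors.append((int(idx) + 2, col.name, "not a number"))
            series = coerced
            df[col.name] = coerced
        if col.check is not None:
            bad = col.check(series).fillna(False)
            for idx in df.index[bad]:
                errors.append((int(idx) + 2, col.name, col.message))

    if schema.unique_key:
        dup = df.duplicated(list(schema.unique_key), keep="first")
        for idx in df.index[dup]:
            errors.append((int(idx) + 2, "+".join(schema.unique_key), "duplicate key"))

    if errors:
        report = "; ".join(f"line {ln}: {col}: {msg}" for ln, col, msg in errors)
        raise SchemaError(f"{path}: {len(errors)} constraint violation(s): {report}", errors)
    return df


def _to_md(df: pd.DataFrame) -> str:
    try:
        return df.to_markdown(index=False)
    except ImportError:  # tabulate unavailable
        return df.to_string(index=False)


def _fmt(x, ndigits=1) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    return f"{round_half_up(float(x), ndigits):.{ndigits}f}"


def build_report(results: dict) -> Dict[str, object]:
    """Assemble publication-style summary tables from module results.

    ``results`` may carry any of:

    * ``tissue_summary`` -- output of ``summarize_tissue``; optionally
      ``tissue_ratios`` alongside;
    * ``survival_summary`` -- output of ``SurvivalStudyResults.summary()``;
    * ``dose_rows`` -- list of dicts with group/physical/photon-equivalent
      entries (None for unknown-factor cells, rendered blank).

    Returns ``{"tables": {name: DataFrame}, "markdown": str}``; display
    values are one-decimal half-up strings, full-precision columns keep
    the ``_exact`` suffix.  Partial bundles are fine; an empty bundle
    yields an empty report.
    """
    tables: Dict[str, pd.DataFrame] = {}
    md: List[str] = []

    ts = results.get("tissue_summary")
    if ts is not None:
        disp = ts.copy()
        disp["mean_exact"] = disp["mean"]
        disp["sd_exact"] = disp["sd"]
        disp["mean"] = disp["mean_exact"].map(_fmt)
        disp["sd"] = disp["sd_exact"].map(_fmt)
        ratios = results.get("tissue_ratios")
        if ratios is not None:
            r = ratios.copy()
            r["t_br_exact"], r["t_bl_exact"] = r["t_br"], r["t_bl"]
            r["t_br"], r["t_bl"] = r["t_br_exact"].map(_fmt), r["t_bl_exact"].map(_fmt)
            tables["tissue_ratios"] = r
        tables["tissue_summary"] = disp
        md.append("## Boron concentration (ug B/g)\n\n" + _to_md(disp))

    ss = results.get("survival_summary")
    if ss is not None:
        disp = ss.copy()
        for c in ("mean", "sd", "median", "pct_ils"):
            if c in disp:
                disp[f"{c}_exact"] = disp[c]
                disp[c] = disp[f"{c}_exact"].map(_fmt)
        tables["survival_summary"] = disp
        md.append("## Survival time (days)\n\n" + _to_md(disp))

    dr = results.get("dose_rows")
    if dr is not None:
        disp = pd.DataFrame(
            [
                {
                    "group": row.get("group", ""),
                    "physical_brain": _fmt(row.get("physical_brain")),
                    "physical_tumor": _fmt(row.get("physical_tumor")),
                    "eq_brain": _fmt(row.get("eq_brain")),
                    "eq_tumor": _fmt(row.get("eq_tumor")),
                }
                for row in dr
            ]
        )
        tables["dose_table"] = disp
        md.append("## Physical and photon-equivalent dose (Gy / Gy-Eq)\n\n" + _to_md(disp))

    return {"tables": tables, "markdown": "\n\n".join(md) if md else ""}
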