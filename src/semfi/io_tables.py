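"""Reading, writing and standardizing soil-sample tables.

A soil-sample table is a long-format :class:`pandas.DataFrame` with one row
per physical soil core: identifying metadata (stand age group I-V, replicate
plot 1-5, sampling point 1-5, depth layer) and six nutrient indicators —
soil organic matter (SOM), total nitrogen (TN) and total phosphorus (TP) in
g/kg, and available nitrogen (AN), available phosphorus (AP) and available
potassium (AK) in mg/kg.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateColumnError, SchemaError, ValidationError

#: Canonical indicator column names, in reporting order.
INDICATORS: tuple[str, ...] = ("som", "tn", "tp", "an", "ap", "ak")

#: Indicator measurement units, for reports.
INDICATOR_UNITS: dict[str, str] = {
    "som": "g/kg",
    "tn": "g/kg",
    "tp": "g/kg",
    "an": "mg/kg",
    "ap": "mg/kg",
    "ak": "mg/kg",
}

#: Metadata columns preceding the indicators.
META_COLUMNS: tuple[str, ...] = ("sample_id", "age_group", "plot", "point", "depth_layer")

#: Stand age groups, young to over-mature.
AGE_GROUPS: tuple[str, ...] = ("I", "II", "III", "IV", "V")

#: Depth layers in cm, fixed four-level ordered set.
DEPTH_LAYERS: tuple[str, ...] = ("0-15", "15-30", "30-45", "45-60")

REQUIRED_COLUMNS: tuple[str, ...] = META_COLUMNS + INDICATORS


def _as_categorical(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["age_group"] = pd.Categorical(table["age_group"], categories=AGE_GROUPS, ordered=True)
    table["depth_layer"] = pd.Categorical(
        table["depth_layer"].astype(str), categories=DEPTH_LAYERS, ordered=True
    )
    return table


def validate_soil_table(table: pd.DataFrame) -> list[str]:
    """Check soil-sample invariants; return one message per violation.

    Checks: all six indicators finite and non-negative; depth layers drawn
    from the fixed four-level set; age groups from I-V; and uniqueness of
    (age_group, plot, point, depth_layer) tuples.  Row numbers in messages
    are 0-based positions in the table.
    """
    problems: list[str] = []
    for col in INDICATORS:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = ~np.isfinite(values.to_numpy(dtype=float)) | (values.to_numpy(dtype=float) < 0)
        for pos in np.nonzero(bad)[0]:
            problems.append(f"row {pos}: {col} = {table[col].iloc[pos]!r} (must be finite and >= 0)")
    bad_depth = ~table["depth_layer"].astype(str).isin(DEPTH_LAYERS)
    for pos in np.nonzero(bad_depth.to_numpy())[0]:
        problems.append(
            f"row {pos}: depth_layer = {table['depth_layer'].iloc[pos]!r} "
            f"(must be one of {DEPTH_LAYERS})"
        )
    bad_age = ~table["age_group"].astype(str).isin(AGE_GROUPS)
    for pos in np.nonzero(bad_age.to_numpy())[0]:
        problems.append(
            f"row {pos}: age_group = {table['age_group'].iloc[pos]!r} (must be one of {AGE_GROUPS})"
        )
    design = table[["age_group", "plot", "point", "depth_layer"]].astype(str)
    dup = design.duplicated(keep=False)
    for pos in np.nonzero(dup.to_numpy())[0]:
        problems.append(
            "row %d: duplicate design cell (age_group=%s, plot=%s, point=%s, depth_layer=%s)"
            % (pos, *design.iloc[pos])
        )
    return problems


def read_soil_table(
    path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read and validate a delimited soil-sample table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    schema
        Optional mapping from canonical column names to the names used in
        the file, e.g. ``{"som": "SOM_g_kg"}``.
    delimiter
        Field delimiter, ``","`` by default.

    Returns
    -------
    pandas.DataFrame
        Validated table with canonical columns, ordered categorical
        ``age_group`` and ``depth_layer``, and float indicator columns.

    Raises
    ------
    SchemaError
        If a required column is missing or an indicator cell is non-numeric.
    ValidationError
        If rows violate the sample invariants; ``err.report`` lists them.
    """
    raw = pd.read_csv(path, delimiter=delimiter, dtype=str)
    rename = {v: k for k, v in (schema or {}).items()}
    raw = raw.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    table = raw[list(REQUIRED_COLUMNS)].copy()
    bad_cells = []
    for col in INDICATORS:
        # parse with Python's float(): correctly rounded, so values written at
        # full precision round-trip bit-identically
        parsed = np.full(len(table), np.nan)
        for pos, cell in enumerate(table[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            try:
                parsed[pos] = float(cell)
            except ValueError:
                bad_cells.append(f"row {pos}, column {col}: {cell!r}")
        table[col] = parsed
    if bad_cells:
        raise SchemaError("non-numeric indicator cell(s): " + "; ".join(bad_cells))
    if table[list(INDICATORS)].isna().any().any():
        na_rows = np.nonzero(table[list(INDICATORS)].isna().any(axis=1).to_numpy())[0]
        raise ValidationError(
            "missing indicator values (complete cases required)",
            report=[f"row {pos}: missing indicator value" for pos in na_rows],
        )
    table["plot"] = pd.to_numeric(table["plot"]).astype(int)
    table["point"] = pd.to_numeric(table["point"]).astype(int)

    problems = validate_soil_table(table)
    if problems:
        raise ValidationError(
            f"{len(problems)} row(s) violate soil-sample invariants", report=problems
        )
    return _as_categorical(table)


def write_soil_table(table: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write a soil-sample table as delimited UTF-8 text at full precision."""
    table.to_csv(path, sep=delimiter, index=False)


def zscore_normalize(
    table: pd.DataFrame,
    columns: Sequence[str] = INDICATORS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score the named columns (sample SD, denominator n-1).

    Returns a standardized copy together with the per-column (mean, sd)
    actually used, so raw-scale values remain recoverable via
    ``raw = z * sd + mean``.

    Raises
    ------
    DegenerateColumnError
        If any named column is constant (sd = 0).
    """
    out = table.copy()
    stats = {}
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if not np.isfinite(sd) or sd <= 0.0:
            raise DegenerateColumnError(f"column {col!r} has zero variance; cannot z-score")
        out[col] = (x - mean) / sd
        stats[col] = {"mean": mean, "sd": sd}
    stats_frame = pd.DataFrame(stats).T.rename_axis("indicator")
    return out, stats_frame


def inverse_zscore(
    table: pd.DataFrame, stats: pd.DataFrame, columns: Iterable[str] | None = None
) -> pd.DataFrame:
    """Undo :func:`zscore_normalize` using its returned (mean, sd) frame."""
    out = table.copy()
    for col in columns if columns is not None else stats.index:
        out[col] = out[col].to_numpy(dtype=float) * stats.loc[col, "sd"] + stats.loc[col, "mean"]
    return out
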