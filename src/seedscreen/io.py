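"""Validated table I/O.

All interchange is CSV (UTF-8, dot decimal).  Schemas:

* ``organ`` — genotype_id, ecotype_ref, plate_id, replicate_id, condition,
  hypocotyl_length_mm, root_length_mm, [hypocotyl_width_mm]
* ``cellfile`` — root_id, condition, genotype_id, cell_index (1-based from
  the QC), length_um, width_um
* ``mitotic`` — condition, root_id, count

A mapping-driven spreadsheet reader is provided for validation runs against
externally supplied workbooks; the caller names the sheet and the column
mapping, nothing is hard-coded.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

SCHEMAS = {
    "organ": {
        "required": ["genotype_id", "ecotype_ref", "plate_id", "replicate_id",
                     "condition", "hypocotyl_length_mm", "root_length_mm"],
        "optional": ["hypocotyl_width_mm"],
        "positive": ["hypocotyl_length_mm", "root_length_mm", "hypocotyl_width_mm"],
    },
    "cellfile": {
        "required": ["root_id", "condition", "genotype_id", "cell_index",
                     "length_um", "width_um"],
        "optional": [],
        "positive": ["length_um", "width_um"],
    },
    "mitotic": {
        "required": ["condition", "root_id", "count"],
        "optional": [],
        "positive": [],
    },
}


def validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    """Validate column names, positivity and (for cell files) indexing."""
    if schema not in SCHEMAS:
        raise InputError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise InputError(f"{schema} table missing columns: {missing}")
    for col in spec["positive"]:
        if col not in df.columns:
            continue
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() | (values <= 0)]
        if len(bad):
            raise InputError(
                f"{schema} table: non-positive or non-numeric {col} at rows {list(bad[:5])}")
    if schema == "cellfile":
        idx = pd.to_numeric(df["cell_index"], errors="coerce")
        if idx.isna().any() or (idx < 1).any() or (idx != idx.astype(int)).any():
            raise InputError("cell_index must be 1-based positive integers")
        dup = df.duplicated(subset=["root_id", "cell_index"])
        if dup.any():
            pairs = df.loc[dup, ["root_id", "cell_index"]].head(5).to_records(index=False)
            raise InputError(f"duplicate (root_id, cell_index) pairs: {list(pairs)}")
    if schema == "mitotic":
        counts = pd.to_numeric(df["count"], errors="coerce")
        if counts.isna().any() or (counts < 0).any():
            raise InputError("mitotic counts must be non-negative numbers")
    return df


def read_measurements(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a measurement CSV."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    return validate_table(pd.read_csv(path), schema)


def read_workbook(
    path: str | Path,
    sheet: str,
    column_mapping: dict[str, str],
    schema: str,
) -> pd.DataFrame:
    """Read one sheet of a spreadsheet workbook using a user-supplied mapping.

    ``column_mapping`` maps schema column names to workbook column headers
    (the internal layout of supplementary workbooks varies, so it is never
    guessed).  The renamed table is validated against ``schema``.
    """
    df = pd.read_excel(Path(path), sheet_name=sheet, engine="openpyxl")
    missing = [src for src in column_mapping.values() if src not in df.columns]
    if missing:
        raise InputError(f"workbook sheet {sheet!r} lacks columns: {missing}")
    out = df[[v for v in column_mapping.values()]].copy()
    out.columns = list(column_mapping.keys())
    return validate_table(out, schema)


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path
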