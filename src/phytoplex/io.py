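"""Schema-validated CSV/JSON/YAML readers and writers.

All tables are UTF-8 CSV with a header row and dot-decimal numbers; a
decimal comma in a numeric cell is rejected with an explicit message rather
than silently parsed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .calibration import CalibrationCurve
from .errors import ParseError

__all__ = [
    "TableSchema",
    "METABOLITE_SCHEMA",
    "RESPONSE_SCHEMA",
    "PLATE_SCHEMA",
    "DESIGN_SCHEMA",
    "FRAGMENT_SCHEMA",
    "read_table",
    "write_table",
    "read_curve",
    "write_curve",
    "load_yaml_config",
]


class TableSchema:
    """Required columns of a table and which of them must be numeric."""

    def __init__(self, name: str, required: Sequence[str],
                 numeric: Sequence[str] = (), numeric_rest: bool = False):
        self.name = name
        self.required = list(required)
        self.numeric = list(numeric)
        self.numeric_rest = numeric_rest  # every non-required column is numeric


METABOLITE_SCHEMA = TableSchema(
    "metabolite_table",
    required=["sample_id", "cultivar", "vintage", "replicate"],
    numeric=["replicate"],
    numeric_rest=True,
)
RESPONSE_SCHEMA = TableSchema(
    "response_table", required=["sample_id", "teac"], numeric=["teac"]
)
PLATE_SCHEMA = TableSchema(
    "plate_table",
    required=["sample_id", "role", "replicate", "absorbance"],
    numeric=["replicate", "absorbance"],
)
DESIGN_SCHEMA = TableSchema(
    "design_table",
    required=["design", "condition", "compound", "class", "concentration_mg_per_ml"],
    numeric=[],
)
FRAGMENT_SCHEMA = TableSchema(
    "fragment_table",
    required=["precursor_mz", "level", "parent_mz", "fragment_mz"],
    numeric=["precursor_mz", "parent_mz", "fragment_mz"],
)


def _check_numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    raw = df[col].astype(str).str.strip()
    converted = pd.to_numeric(raw, errors="coerce")
    bad = converted.isna() & raw.ne("") & raw.str.lower().ne("nan")
    if bad.any():
        row = int(bad.idxmax())
        value = raw.loc[row]
        if "," in value:
            raise ParseError(
                f"{path}: column {col!r}, row {row}: decimal comma in {value!r} "
                "— use dot-decimal CSV"
            )
        raise ParseError(
            f"{path}: column {col!r}, row {row}: non-numeric value {value!r}"
        )
    return converted


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read a CSV and validate it against a schema.

    Numeric columns are converted; missing required columns and non-numeric
    cells raise :class:`ParseError` naming the offending column/row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: {schema.name} missing required column(s): {missing}"
        )
    numeric_cols = list(schema.numeric)
    if schema.numeric_rest:
        numeric_cols += [c for c in df.columns if c not in schema.required]
    for col in numeric_cols:
        df[col] = _check_numeric(df, col, path)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = df.reset_index() if df.index.name else df
    out.to_csv(path, index=False)


def read_curve(path) -> CalibrationCurve:
    return CalibrationCurve.from_json(Path(path).read_text())


def write_curve(curve: CalibrationCurve, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(curve.to_json())


def load_yaml_config(path, known_keys: Mapping[str, type] | Sequence[str]) -> dict:
    """Load a flat YAML key:value config, rejecting unknown keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    known = set(known_keys)
    unknown = [k for k in data if k not in known]
    if unknown:
        raise ParseError(f"{path}: unknown config key(s): {sorted(unknown)}")
    return data


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(x):
    try:
        import numpy as np
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
    except Exception:
        pass
    raise TypeError(f"not JSON serializable: {type(x)}")
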