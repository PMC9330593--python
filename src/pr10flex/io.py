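"""Reading peak-intensity tables and writing result files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import SCHEMA_VERSION

__all__ = ["read_peak_table", "write_json", "write_csv"]

REQUIRED_COLUMNS = ("residue", "field_mhz", "nu_cpmg_hz", "intensity", "i0")

#: Default column map for nmrPipe-style whitespace tables: source column
#: name (or 0-based index) -> tidy schema column.
DEFAULT_TAB_COLUMN_MAP = {
    "RESID": "residue",
    "FIELD": "field_mhz",
    "NU_CPMG": "nu_cpmg_hz",
    "HEIGHT": "intensity",
    "HEIGHT0": "i0",
    "REP": "replicate_id",
}


def read_peak_table(path, dialect: str = "tidy_csv",
                    column_map: dict | None = None) -> pd.DataFrame:
    """Read an intensity table in tidy-CSV or nmrPipe-style dialect.

    The nmrPipe-style dialect is whitespace-delimited with ``VARS``/
    ``FORMAT`` header lines (ignored beyond column naming) or a plain
    header row; ``column_map`` renames source columns onto the tidy schema
    (residue, field_mhz, nu_cpmg_hz, intensity, i0[, replicate_id]).
    Malformed rows and duplicate (residue, field, nu, replicate) keys are
    errors naming the offending line or key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tidy_csv":
        df = pd.read_csv(path)
    elif dialect == "nmrpipe_tab":
        df = _read_nmrpipe_tab(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "replicate_id" not in df.columns:
        df["replicate_id"] = 0
    bad = df[~np.isfinite(df[["field_mhz", "nu_cpmg_hz", "intensity", "i0"]]).all(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: non-numeric values in rows {bad.index.tolist()}")
    res = pd.to_numeric(df["residue"], errors="coerce")
    if res.isna().any() or (res <= 0).any() or (res != res.astype(int)).any():
        raise ValueError(f"{path}: residue ids must be positive integers")
    df["residue"] = res.astype(int)
    key = ["residue", "field_mhz", "nu_cpmg_hz", "replicate_id"]
    dup = df[df.duplicated(key, keep=False)]
    if len(dup):
        first = dup.iloc[0]
        raise ValueError(
            f"{path}: duplicate entry for residue {first.residue} at "
            f"{first.field_mhz} MHz, {first.nu_cpmg_hz} Hz, replicate {first.replicate_id}")
    return df


def _read_nmrpipe_tab(path: Path) -> pd.DataFrame:
    """Parse a whitespace-delimited peak table with VARS/FORMAT headers."""
    names = None
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("REMARK", "#", "DATA")):
            continue
        if stripped.startswith("VARS"):
            names = stripped.split()[1:]
            continue
        if stripped.startswith("FORMAT"):
            continue
        fields = stripped.split()
        if names is None:
            # first non-header line doubles as a header row
            names = fields
            continue
        if len(fields) != len(names):
            raise ValueError(f"{path}:{lineno}: expected {len(names)} fields, got {len(fields)}")
        rows.append(fields)
    if names is None:
        raise ValueError(f"{path}: no header found")
    df = pd.DataFrame(rows, columns=names)
    for c in df.columns:
        conv = pd.to_numeric(df[c], errors="coerce")
        if not conv.isna().any():
            df[c] = conv
    return df


def write_json(obj, path) -> None:
    """Write a result dict as JSON with the schema version stamped in."""
    path = Path(path)
    payload = {"schema_version": SCHEMA_VERSION}
    payload.update(obj)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=1))


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (bool, int, float, str)) or x is None:
        return x
    return str(x)


def write_csv(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
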