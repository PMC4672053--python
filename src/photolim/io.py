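"""CSV readers/writers for gas-exchange + fluorescence tables.

The native interchange format is plain CSV with one row per measurement
point.  Column names are resolved through a *dialect*: a mapping from
the canonical field names used here to the column names present in the
file, plus a declaration of the basis on which stomatal conductance is
reported (``"H2O"`` or ``"CO2"``).  Raw instrument text files are not
parsed.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml

from .errors import EmptyInputError, SchemaError, ShapeError
from .types import GSW_TO_GSC, ACiCurve, FluorescenceRecord, GasExchangeRecord

log = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("A_N", "C_a", "C_i", "g_sw", "PPFD")
OPTIONAL_GAS_COLUMNS = ("T_r", "T_leaf", "VPD")
FLUORESCENCE_COLUMNS = ("F_s", "F_m_prime", "F_o_prime", "F_o", "F_m")
GROUP_COLUMNS = ("leaf_id", "treatment", "day")

#: Identity dialect: file columns already use canonical names and g_s is
#: on a water-vapor basis.
DEFAULT_DIALECT: dict = {
    "columns": {},
    "gs_basis": "H2O",
}


def load_dialect(path: Union[str, Path]) -> dict:
    """Load a column-map/dialect config from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        d = json.loads(text)
    else:
        d = yaml.safe_load(text)
    out = dict(DEFAULT_DIALECT)
    out.update(d or {})
    out["columns"] = {**DEFAULT_DIALECT["columns"], **(out.get("columns") or {})}
    if out.get("gs_basis") not in ("H2O", "CO2"):
        raise SchemaError(f"gs_basis must be 'H2O' or 'CO2', got {out.get('gs_basis')!r}")
    return out


def _resolve(dialect: Mapping, canonical: str) -> str:
    return dialect.get("columns", {}).get(canonical, canonical)


def read_curve_csv(
    path: Union[str, Path],
    dialect: Optional[Mapping] = None,
) -> list[ACiCurve]:
    """Read a points table and group it into A–C_i curves.

    One :class:`~photolim.types.ACiCurve` is produced per
    ``(leaf_id, treatment, day)`` group, points kept in file order.
    Rows whose numeric fields fail coercion are rejected; their row
    numbers are logged.

    Raises
    ------
    SchemaError
        If a mandatory column cannot be resolved.
    EmptyInputError
        If the file holds no data rows.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} contains no data") from None
    if df.empty:
        raise EmptyInputError(f"{path} contains no data rows")

    for canonical in MANDATORY_COLUMNS:
        col = _resolve(dialect, canonical)
        if col not in df.columns:
            raise SchemaError(f"mandatory column {canonical!r} (file column {col!r}) is missing")

    rename = {}
    for canonical in (
        MANDATORY_COLUMNS + OPTIONAL_GAS_COLUMNS + FLUORESCENCE_COLUMNS + GROUP_COLUMNS
    ):
        col = _resolve(dialect, canonical)
        if col in df.columns:
            rename[col] = canonical
    df = df.rename(columns=rename)

    numeric = [
        c
        for c in MANDATORY_COLUMNS + OPTIONAL_GAS_COLUMNS + FLUORESCENCE_COLUMNS
        if c in df.columns
    ]
    coerced = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = coerced[list(MANDATORY_COLUMNS)].isna().any(axis=1)
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad]]  # 1-based incl. header
        log.warning("rejected %d row(s) failing numeric coercion: file lines %s", len(rows), rows)
    df[numeric] = coerced
    df = df[~bad]
    if df.empty:
        raise EmptyInputError(f"{path}: every row failed coercion")

    if "leaf_id" not in df.columns:
        df["leaf_id"] = "leaf0"
    if "treatment" not in df.columns:
        df["treatment"] = "unknown"
    if "day" not in df.columns:
        df["day"] = 0

    gs_factor = GSW_TO_GSC if dialect.get("gs_basis") == "CO2" else 1.0

    curves = []
    for (leaf_id, treatment, day), grp in df.groupby(
        ["leaf_id", "treatment", "day"], sort=False
    ):
        points = []
        for _, row in grp.iterrows():
            gas = GasExchangeRecord(
                A_N=row["A_N"],
                C_a=row["C_a"],
                C_i=row["C_i"],
                g_sw=row["g_sw"] * gs_factor,
                PPFD=row["PPFD"],
                T_r=_opt(row, "T_r"),
                T_leaf=_opt(row, "T_leaf"),
                VPD=_opt(row, "VPD"),
            )
            fluo = None
            if "F_s" in grp.columns and not math.isnan(row.get("F_s", float("nan"))):
                fluo = FluorescenceRecord(
                    F_s=row["F_s"],
                    F_m_prime=row["F_m_prime"],
                    F_o_prime=_opt(row, "F_o_prime"),
                    F_o=_opt(row, "F_o"),
                    F_m=_opt(row, "F_m"),
                )
            points.append((gas, fluo))
        curves.append(
            ACiCurve(leaf_id=str(leaf_id), treatment=str(treatment), day=int(day), points=points)
        )
    return curves


def _opt(row, name):
    if name not in row.index:
        return None
    v = row[name]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def write_results_csv(results: Union[pd.DataFrame, Mapping], path: Union[str, Path]) -> Path:
    """Write a table of named numeric columns to CSV.

    Floats are written in shortest round-trip representation, so a
    read-back agrees with the in-memory values to (at least) 12
    significant digits.

    Raises
    ------
    ShapeError
        If the columns have unequal lengths.
    """
    if not isinstance(results, pd.DataFrame):
        lengths = {k: len(v) for k, v in results.items()}
        if len(set(lengths.values())) > 1:
            raise ShapeError(f"ragged columns: {lengths}")
        results = pd.DataFrame(dict(results))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(path, index=False)
    return path
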