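"""Delimited-text table formats, fit reports and run manifests.

Curve tables are long-format delimited text with header columns
``label, pO2_mmHg, saturation`` (or ``saturation_percent``) and optional
``effector_id, effector_conc``; one curve per (label, effector_id,
effector_conc) group.  Parameter tables carry ``species, L`` and either
(``K_R``, ``K_T``) or (``c``, ``K_T``).  The delimiter is auto-detected
between comma and tab; everything written back out is tab-delimited with a
header.  Saturation is always a fraction internally; percent columns are
converted at the boundary.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import SaturationCurve

__all__ = [
    "ParseError",
    "read_saturation_table",
    "write_saturation_table",
    "read_parameter_table",
    "write_parameter_table",
    "write_table",
    "write_fit_report",
    "write_manifest",
]

logger = logging.getLogger("hillscape")

_CURVE_KEYS = ["label", "effector_id", "effector_conc"]


class ParseError(ValueError):
    """Raised when an input table is malformed; message names the row."""


def _read_delimited(path: Union[str, Path]) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with a header row."""
    path = Path(path)
    if not path.read_text().strip():
        return pd.DataFrame()
    try:
        return pd.read_csv(path, sep=None, engine="python", comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    except Exception as exc:  # surface the offending file uniformly
        raise ParseError(f"{path}: cannot parse delimited table ({exc})") from exc


def _numeric(df: pd.DataFrame, column: str, path: Path) -> pd.Series:
    out = pd.to_numeric(df[column], errors="coerce").astype(float)
    bad = out.isna() & df[column].notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based, plus header line
        raise ParseError(
            f"{path}: non-numeric value {df[column][bad.idxmax()]!r} in column "
            f"'{column}' at line {row}"
        )
    return out


def read_saturation_table(path: Union[str, Path]) -> List[SaturationCurve]:
    """Read saturation curves from a delimited text file.

    Saturation may be a fraction (column ``saturation``) or a percent
    (column ``saturation_percent`` or ``saturation_pct``); percent columns
    are divided by 100.  Rows are grouped by (label, effector_id,
    effector_conc) and sorted by pressure, with a warning when sorting was
    needed.
    """
    path = Path(path)
    df = _read_delimited(path)
    if df.empty:
        logger.warning("%s: empty saturation table", path)
        return []
    pct_cols = [c for c in df.columns if c in ("saturation_percent", "saturation_pct")]
    if "saturation" in df.columns and pct_cols:
        raise ParseError(f"{path}: both fraction and percent saturation columns present")
    required = {"label", "pO2_mmHg"} | ({"saturation"} if not pct_cols else set(pct_cols[:1]))
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    sat_col = "saturation" if not pct_cols else pct_cols[0]
    df = df.copy()
    df["pO2_mmHg"] = _numeric(df, "pO2_mmHg", path)
    df[sat_col] = _numeric(df, sat_col, path)
    limit = 1.0 if sat_col == "saturation" else 100.0
    bad = (df[sat_col] < 0) | (df[sat_col] > limit)
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise ParseError(
            f"{path}: saturation {df[sat_col][bad.idxmax()]} outside [0, {limit:g}] "
            f"at line {row}"
        )
    y = df[sat_col] / limit
    df["_fraction"] = y
    for key in ("effector_id", "effector_conc"):
        if key not in df.columns:
            df[key] = None
    curves = []
    group_cols = ["label", "effector_id", "effector_conc"]
    for keys, grp in df.groupby(group_cols, dropna=False, sort=True):
        label, eff_id, eff_conc = keys
        if not grp["pO2_mmHg"].is_monotonic_increasing:
            logger.warning(
                "%s: rows for curve %r were not pressure-sorted; sorting", path, label
            )
        grp = grp.sort_values("pO2_mmHg")
        try:
            curves.append(
                SaturationCurve(
                    pressures=grp["pO2_mmHg"].to_numpy(),
                    saturations=grp["_fraction"].to_numpy(),
                    label=str(label),
                    effector_id=None if pd.isna(eff_id) else str(eff_id),
                    effector_conc=None if pd.isna(eff_conc) else float(eff_conc),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: curve {label!r}: {exc}") from exc
    return curves


def write_saturation_table(
    curves: Sequence[SaturationCurve], path: Union[str, Path]
) -> None:
    """Write curves as a tab-delimited long-format table (fractions)."""
    rows = []
    for cu in curves:
        for p, y in zip(cu.pressures, cu.saturations):
            rows.append(
                {
                    "label": cu.label,
                    "pO2_mmHg": p,
                    "saturation": y,
                    "effector_id": cu.effector_id if cu.effector_id is not None else "",
                    "effector_conc": cu.effector_conc
                    if cu.effector_conc is not None
                    else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_parameter_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a per-species (L, c, K_R, K_T) parameter table.

    Requires columns ``species`` and ``L``, plus either (``K_R`` and
    ``K_T``) or (``c`` and ``K_T``).  Rows are returned with all of c, K_R
    and K_T populated; if both c and K_R/K_T are supplied they must agree
    to 1%.
    """
    path = Path(path)
    df = _read_delimited(path)
    if df.empty:
        logger.warning("%s: empty parameter table", path)
        return pd.DataFrame(columns=["species", "L", "c", "K_R", "K_T"])
    if "species" not in df.columns or "L" not in df.columns:
        raise ParseError(f"{path}: parameter table needs 'species' and 'L' columns")
    has_KR = "K_R" in df.columns
    has_c = "c" in df.columns
    if "K_T" not in df.columns or not (has_KR or has_c):
        raise ParseError(
            f"{path}: need 'K_T' plus one of 'K_R' or 'c' to fix the affinity scale"
        )
    df = df.copy()
    for col in ["L", "K_T"] + (["K_R"] if has_KR else []) + (["c"] if has_c else []):
        df[col] = _numeric(df, col, path)
    if has_KR and has_c:
        implied = df["K_R"] / df["K_T"]
        rel = (implied - df["c"]).abs() / df["c"]
        if (rel > 0.01).any():
            i = int(rel.idxmax())
            raise ParseError(
                f"{path}: c and K_R/K_T disagree by {rel[i]*100:.1f}% "
                f"for species {df['species'][i]!r} (line {i + 2})"
            )
    if has_c and not has_KR:
        df["K_R"] = df["c"] * df["K_T"]
    if has_KR and not has_c:
        df["c"] = df["K_R"] / df["K_T"]
    bad = (df["L"] < 0) | (df["K_R"] <= 0) | (df["K_T"] <= 0)
    if bad.any():
        i = int(bad.idxmax())
        raise ParseError(
            f"{path}: invalid parameter values for species {df['species'][i]!r} "
            f"(line {i + 2})"
        )
    return df[["species", "L", "c", "K_R", "K_T"]]


def write_parameter_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write any analysis DataFrame as tab-delimited text with a header."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_fit_report(report: dict, path: Union[str, Path]) -> None:
    """Serialize a fit report (parameters, errors, R^2, flags) as JSON."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2) + "\n")


def write_manifest(
    path: Union[str, Path],
    command: str,
    config: dict,
    outputs: Sequence[str],
    seed: Optional[int] = None,
    exit_code: int = 0,
) -> None:
    """Write the run manifest: effective config, outputs, versions, seed."""
    from . import __version__

    manifest = {
        "command": command,
        "config": _jsonable(config),
        "outputs": list(outputs),
        "seed": seed,
        "exit_code": exit_code,
        "versions": {
            "hillscape": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def _jsonable(obj):
    """Recursively coerce numpy scalars/arrays and dataclasses for JSON."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj
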