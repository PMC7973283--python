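"""Reading cohort tables and writing pipeline reports.

CSV (UTF-8, header row, one subject per row) is the canonical input format;
``.xlsx`` files are accepted through a thin pandas/openpyxl adapter.  Empty
cells, ``NA`` and ``NaN`` all map to missing.  Orientation is auto-detected:
if the chronological-age label appears in the first column instead of the
header, the table is transposed (biomarkers-as-rows layouts occur in the
wild).
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .cohort import BiomarkerSpec, CohortError, CohortTable

logger = logging.getLogger("bioage")

__all__ = ["read_cohort", "read_biomarker_specs", "write_report", "read_report"]

_NA_TOKENS = ["", "NA", "NaN", "nan", "na", "n/a", "N/A", "None", "-"]


def _load_frame(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path, header=0, na_values=_NA_TOKENS, dtype=object)
    return pd.read_csv(path, header=0, na_values=_NA_TOKENS,
                       keep_default_na=True, dtype=object, skipinitialspace=True)


def read_cohort(path: str | Path,
                ca_column: str = "CA",
                group_column: str | None = None,
                id_column: str | None = None) -> CohortTable:
    """Read and validate a cohort table.

    Rows whose chronological age is missing, non-numeric or non-positive are
    dropped with a warning; non-numeric biomarker cells become missing.

    Raises
    ------
    CohortError
        If the CA column is absent or fewer than 2 valid subjects remain.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"no such file: {path}")
    frame = _load_frame(path)

    if ca_column not in frame.columns:
        first = frame.iloc[:, 0].astype(str)
        if (first == ca_column).any():
            # biomarkers-as-rows layout: first column holds the labels
            frame = frame.set_index(frame.columns[0]).T.reset_index(drop=True)
            frame.columns.name = None
        else:
            raise CohortError(f"CA column {ca_column!r} not found in {path}")

    if id_column is None and len(frame.columns):
        cand = frame.columns[0]
        if cand != ca_column and cand != group_column:
            if pd.to_numeric(frame[cand], errors="coerce").isna().all():
                id_column = cand

    if id_column is not None:
        index = pd.Index(frame[id_column].astype(str), name="subject")
        frame = frame.drop(columns=[id_column])
    else:
        index = pd.Index([f"S{i + 1:04d}" for i in range(len(frame))], name="subject")
    frame.index = index

    group = None
    if group_column is not None:
        if group_column not in frame.columns:
            raise CohortError(f"group column {group_column!r} not found")
        group = frame[group_column].astype(str)
        frame = frame.drop(columns=[group_column])

    ca = pd.to_numeric(frame[ca_column], errors="coerce").astype(float)
    data = frame.drop(columns=[ca_column]).apply(
        lambda col: pd.to_numeric(col, errors="coerce"), axis=0).astype(float)

    keep = ca.notna() & np.isfinite(ca) & (ca > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d subject(s) with missing/invalid CA: %s",
                       n_dropped, list(data.index[~keep]))
    data, ca = data.loc[keep], ca.loc[keep]
    if group is not None:
        group = group.loc[keep]

    if len(data) < 2:
        raise CohortError(f"fewer than 2 valid subjects in {path}")
    if data.shape[1] < 1:
        raise CohortError(f"no biomarker columns in {path}")
    return CohortTable(data, ca, group)


def read_biomarker_specs(path: str | Path) -> list[BiomarkerSpec]:
    """Read a biomarker metadata table (CSV with a ``name`` column)."""
    frame = pd.read_csv(path, na_values=_NA_TOKENS)
    specs = []
    for _, row in frame.iterrows():
        def _num(key: str) -> float | None:
            v = row.get(key)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        specs.append(BiomarkerSpec(
            name=str(row["name"]),
            units=str(row.get("units", "") or ""),
            instrument_accuracy=_num("instrument_accuracy"),
            reference_change=_num("reference_change"),
            reference_interval=_num("reference_interval"),
        ))
    return specs


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_report(report: dict[str, Any], path: str | Path,
                 formula_path: str | Path | None = None) -> None:
    """Write the machine-readable pipeline report (JSON).

    The report carries every threshold used, each per-step rejection with its
    numeric evidence, the final panel and the cohort statistics.  When
    ``formula_path`` is given the human-readable rendered formula is written
    alongside.
    """
    path = Path(path)
    try:
        path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True,
                                   allow_nan=False) + "\n", encoding="utf-8")
    except OSError as exc:  # unwritable path is fatal
        raise CohortError(f"cannot write report to {path}: {exc}") from exc
    if formula_path is not None:
        text = report.get("formula") or "no panel\n"
        Path(formula_path).write_text(text if text.endswith("\n") else text + "\n",
                                      encoding="utf-8")


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text(encoding="utf-8"))
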