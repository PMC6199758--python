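"""CSV readers and writers for the pipeline's tables.

One canonical dialect everywhere: UTF-8, comma-separated, a single header
row, ``.`` decimal point.  Floats are written with Python's shortest
round-trip representation, so ``write(read(f))`` is byte-identical to the
canonical form of ``f`` and read/write round-trips are lossless.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_STATUS_MAP,
    AnalytePanel,
    EventTable,
    ExpressionMatrix,
    StiffnessExpressionTable,
    SurvivalCurveMatrix,
    ValidationError,
)

__all__ = [
    "read_expression_csv", "write_expression_csv",
    "read_survival_csv", "write_survival_csv",
    "read_event_table_csv", "write_event_table_csv",
    "read_stiffness_csv", "write_stiffness_csv",
    "bundle_to_json", "bundle_from_json",
]


def _fmt(x) -> str:
    """Canonical cell representation: shortest exact repr for floats."""
    if isinstance(x, (float, np.floating)):
        return repr(float(x))
    return str(x)


def _write_rows(path, header, rows) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(header)
        for row in rows:
            w.writerow([_fmt(v) for v in row])


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, index_col=0, dtype=object)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"no groups: {path} is empty") from exc


def read_expression_csv(path, panel: AnalytePanel | None = None) -> ExpressionMatrix:
    """Read a groups x analytes concentration table.

    Header row = analyte names; first column = group label.
    """
    frame = _read_csv(path)
    return ExpressionMatrix(frame, panel=panel)


def write_expression_csv(matrix: ExpressionMatrix, path) -> None:
    f = matrix.frame
    _write_rows(path, ["group", *f.columns],
                ([idx, *row] for idx, row in zip(f.index, f.to_numpy())))


def read_survival_csv(path, allow_nonmonotone: bool = False) -> SurvivalCurveMatrix:
    """Read a groups x timepoints survival-proportion table.

    Header row = timepoints in days; first column = group label.  Rows that
    increase along time beyond tolerance are rejected unless
    ``allow_nonmonotone``.
    """
    frame = _read_csv(path)
    return SurvivalCurveMatrix(frame, allow_nonmonotone=allow_nonmonotone)


def write_survival_csv(matrix: SurvivalCurveMatrix, path) -> None:
    f = matrix.frame
    _write_rows(path, ["group", *(_fmt(t) for t in f.columns)],
                ([idx, *row] for idx, row in zip(f.index, f.to_numpy())))


def read_event_table_csv(path, status_map=None) -> EventTable:
    """Read subject-level event records.

    Columns ``subject,group,time,status``; status tokens are mapped through
    ``status_map`` (default: ``1``/``death`` = event, ``0``/``censored`` =
    censored).
    """
    status_map = {**DEFAULT_STATUS_MAP, **{
        str(k).lower(): bool(v) for k, v in (status_map or {}).items()}}
    raw = pd.read_csv(path, dtype=object)
    missing = [c for c in ("subject", "group", "time", "status")
               if c not in raw.columns]
    if missing:
        raise ValidationError(f"event CSV missing columns {missing}")
    events = []
    for i, tok in enumerate(raw["status"]):
        key = str(tok).strip().lower()
        if key not in status_map:
            raise ValidationError(
                f"unknown status token {tok!r} in row {i} "
                f"(known: {sorted(status_map)})"
            )
        events.append(status_map[key])
    frame = pd.DataFrame({
        "subject": raw["subject"], "group": raw["group"],
        "time": raw["time"].astype(float), "event": events,
    })
    return EventTable(frame)


def write_event_table_csv(table: EventTable, path) -> None:
    f = table.frame
    _write_rows(path, ["subject", "group", "time", "status"],
                ([s, g, t, "death" if e else "censored"]
                 for s, g, t, e in f.itertuples(index=False)))


def read_stiffness_csv(path) -> StiffnessExpressionTable:
    raw = pd.read_csv(path, dtype=object)
    return StiffnessExpressionTable(raw)


def write_stiffness_csv(table: StiffnessExpressionTable, path) -> None:
    f = table.frame
    _write_rows(path, list(f.columns), f.itertuples(index=False))


# ---------------------------------------------------------------------------
# JSON bundle (single-file serialization of any subset of the tables)

def bundle_to_json(path, *, expression=None, survival=None, events=None,
                   stiffness=None, extra=None) -> None:
    """Serialize any subset of the pipeline tables to one JSON file."""
    def frame_obj(fb):
        f = fb.frame
        return {
            "index": [str(i) for i in f.index],
            "columns": [_fmt(c) for c in f.columns],
            "data": [[v if not isinstance(v, (float, np.floating)) else float(v)
                      for v in row] for row in f.itertuples(index=False)],
            "metadata": getattr(fb, "metadata", {}),
        }

    obj = {}
    if expression is not None:
        obj["expression"] = frame_obj(expression)
    if survival is not None:
        obj["survival"] = frame_obj(survival)
    if events is not None:
        f = events.frame.copy()
        obj["events"] = {
            "records": [
                {"subject": str(s), "group": str(g), "time": float(t),
                 "event": bool(e)}
                for s, g, t, e in f.itertuples(index=False)
            ],
            "metadata": events.metadata,
        }
    if stiffness is not None:
        obj["stiffness"] = frame_obj(stiffness)
    if extra:
        obj["extra"] = extra
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n",
                          encoding="utf-8")


def bundle_from_json(path) -> dict:
    """Inverse of :func:`bundle_to_json`; returns a dict of containers."""
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    out: dict = {}
    if "expression" in obj:
        o = obj["expression"]
        out["expression"] = ExpressionMatrix(
            pd.DataFrame(o["data"], index=o["index"], columns=o["columns"]),
            metadata=o.get("metadata"))
    if "survival" in obj:
        o = obj["survival"]
        out["survival"] = SurvivalCurveMatrix(
            pd.DataFrame(o["data"], index=o["index"],
                         columns=[float(c) for c in o["columns"]]),
            metadata=o.get("metadata"), strict=False)
    if "events" in obj:
        o = obj["events"]
        out["events"] = EventTable(pd.DataFrame(o["records"]))
    if "stiffness" in obj:
        o = obj["stiffness"]
        out["stiffness"] = StiffnessExpressionTable(
            pd.DataFrame(o["data"], columns=o["columns"]))
    if "extra" in obj:
        out["extra"] = obj["extra"]
    return out
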