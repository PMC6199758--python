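"""Domain containers for secretome-potency studies.

All tabular data in the pipeline live in one of five validated containers:

* :class:`AnalytePanel` -- the assayed analytes and (optionally) their
  lower limits of detection, in pg/mL.
* :class:`ExpressionMatrix` -- MSC preparations (rows) x secreted-analyte
  concentrations (columns), pg/mL.
* :class:`SurvivalCurveMatrix` -- preparations x timepoints (days),
  survival proportions in [0, 1].
* :class:`EventTable` -- subject-level time-to-event records.
* :class:`StiffnessExpressionTable` -- per-well concentrations with the
  substratum stiffness (kPa) of the culture condition.

Containers wrap a :class:`pandas.DataFrame` and validate their invariants at
construction; every validation error names the offending row/column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "AnalytePanel",
    "ExpressionMatrix",
    "SurvivalCurveMatrix",
    "EventTable",
    "StiffnessExpressionTable",
    "MONOTONE_TOL",
]

#: Tolerance for the non-increasing check on survival rows.  Empirical
#: product-limit curves are exactly non-increasing, so any violation beyond
#: rounding noise signals corrupt input.
MONOTONE_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when a table violates a container invariant."""


def _check_unique(labels: Sequence, what: str) -> None:
    seen: dict = {}
    for i, lab in enumerate(labels):
        if lab in seen:
            raise ValidationError(
                f"duplicate {what} {lab!r} (positions {seen[lab]} and {i})"
            )
        if lab is None or (isinstance(lab, str) and not lab.strip()):
            raise ValidationError(f"empty {what} at position {i}")
        seen[lab] = i


@dataclass(frozen=True)
class AnalytePanel:
    """An ordered set of assayed analytes with optional detection limits.

    Parameters
    ----------
    analyte_names : sequence of str
        Unique, non-empty analyte identifiers, in assay order.
    lod : mapping, optional
        Lower limit of detection per analyte, pg/mL.  Analytes absent from
        the mapping have no known LOD.
    units : str
        Concentration units; fixed to ``"pg/mL"`` for multiplex/ELISA data.
    """

    analyte_names: tuple
    lod: Mapping[str, float] | None = None
    units: str = "pg/mL"

    def __post_init__(self):
        object.__setattr__(self, "analyte_names", tuple(self.analyte_names))
        _check_unique(self.analyte_names, "analyte name")
        if self.lod is not None:
            lod = dict(self.lod)
            for name, v in lod.items():
                if name not in self.analyte_names:
                    raise ValidationError(f"LOD given for unknown analyte {name!r}")
                if not np.isfinite(v) or v < 0:
                    raise ValidationError(f"LOD for {name!r} must be >= 0, got {v}")
            object.__setattr__(self, "lod", lod)

    def __len__(self) -> int:
        return len(self.analyte_names)


class _FrameBacked:
    """Shared plumbing for DataFrame-backed containers."""

    frame: pd.DataFrame

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def shape(self):
        return self.frame.shape

    def __eq__(self, other):
        return type(self) is type(other) and self.frame.equals(other.frame)

    def __repr__(self):  # pragma: no cover - cosmetic
        n, m = self.frame.shape
        return f"<{type(self).__name__} {n}x{m}>"


class ExpressionMatrix(_FrameBacked):
    """Preparations x analytes concentration table (pg/mL).

    Parameters
    ----------
    frame : DataFrame
        Index = preparation (group) labels, columns = analyte names,
        values = concentrations in pg/mL (finite, non-negative).
    panel : AnalytePanel, optional
        If given, columns must match the panel's analytes exactly and in
        order.
    metadata : dict, optional
        Free-form condition metadata (substratum, passage, processing log).
    """

    def __init__(self, frame: pd.DataFrame, panel: AnalytePanel | None = None,
                 metadata: dict | None = None):
        frame = frame.copy()
        if frame.shape[0] == 0:
            raise ValidationError("no groups: expression table has no data rows")
        if frame.shape[1] == 0:
            raise ValidationError("no analytes: expression table has no columns")
        _check_unique(list(frame.index), "group label")
        _check_unique(list(frame.columns), "analyte name")
        try:
            vals = frame.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric concentration value: {exc}") from exc
        bad = ~np.isfinite(vals)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite concentration at group {frame.index[r]!r}, "
                f"analyte {frame.columns[c]!r}"
            )
        neg = vals < 0
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative concentration {vals[r, c]} at group "
                f"{frame.index[r]!r}, analyte {frame.columns[c]!r}"
            )
        if panel is not None and tuple(frame.columns) != tuple(panel.analyte_names):
            raise ValidationError(
                "expression columns do not match the analyte panel: "
                f"got {list(frame.columns)}, panel has {list(panel.analyte_names)}"
            )
        self.frame = frame.astype(float)
        self.panel = panel
        self.metadata = dict(metadata or {})

    @property
    def groups(self) -> list:
        return list(self.frame.index)

    @property
    def analytes(self) -> list:
        return list(self.frame.columns)


class SurvivalCurveMatrix(_FrameBacked):
    """Preparations x timepoints survival-proportion table.

    Rows are survival curves: proportions in [0, 1], non-increasing along
    the (strictly increasing, shared) timepoint grid, equal to 1 at day 0
    when day 0 is present.  Model *predictions* need not satisfy the curve
    invariants; pass ``strict=False`` to store them (the relaxation is
    recorded in ``metadata``).
    """

    def __init__(self, frame: pd.DataFrame, metadata: dict | None = None,
                 strict: bool = True, allow_nonmonotone: bool = False):
        frame = frame.copy()
        if frame.shape[0] == 0:
            raise ValidationError("no groups: survival table has no data rows")
        _check_unique(list(frame.index), "group label")
        try:
            tps = np.asarray([float(t) for t in frame.columns], dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric timepoint header: {exc}") from exc
        if np.any(tps < 0):
            raise ValidationError(f"negative timepoint {tps.min()}")
        if np.any(np.diff(tps) <= 0):
            i = int(np.argmax(np.diff(tps) <= 0))
            raise ValidationError(
                f"timepoints not strictly increasing at column {i + 1} "
                f"({tps[i]} -> {tps[i + 1]})"
            )
        frame.columns = tps
        try:
            vals = frame.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric survival value: {exc}") from exc
        if strict:
            out = (vals < 0) | (vals > 1) | ~np.isfinite(vals)
            if out.any():
                r, c = np.argwhere(out)[0]
                raise ValidationError(
                    f"survival proportion {vals[r, c]} outside [0, 1] at group "
                    f"{frame.index[r]!r}, day {tps[c]}"
                )
            if not allow_nonmonotone:
                incr = np.diff(vals, axis=1) > MONOTONE_TOL
                if incr.any():
                    r, c = np.argwhere(incr)[0]
                    raise ValidationError(
                        f"survival increases along time for group "
                        f"{frame.index[r]!r}: {vals[r, c]} -> {vals[r, c + 1]} "
                        f"between day {tps[c]} and day {tps[c + 1]}"
                    )
            if tps[0] == 0.0:
                off = np.abs(vals[:, 0] - 1.0) > MONOTONE_TOL
                if off.any():
                    r = int(np.argmax(off))
                    raise ValidationError(
                        f"survival at day 0 must be 1, got {vals[r, 0]} for "
                        f"group {frame.index[r]!r}"
                    )
        self.frame = frame.astype(float)
        self.metadata = dict(metadata or {})
        if not strict:
            self.metadata.setdefault("strict", False)

    @property
    def groups(self) -> list:
        return list(self.frame.index)

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray(self.frame.columns, dtype=float)


#: Default mapping from status tokens to the event indicator.
DEFAULT_STATUS_MAP = {
    "1": True, "death": True, "dead": True, "died": True, "event": True,
    "0": False, "censored": False, "censor": False,
}


class EventTable(_FrameBacked):
    """Subject-level time-to-event records.

    Columns: ``subject`` (unique id), ``group`` (cohort label), ``time``
    (days, > 0), ``event`` (bool; True = death, False = censored).
    """

    REQUIRED = ("subject", "group", "time", "event")

    def __init__(self, frame: pd.DataFrame, metadata: dict | None = None):
        frame = frame.copy().reset_index(drop=True)
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValidationError(f"event table missing columns {missing}")
        frame = frame[list(self.REQUIRED)]
        _check_unique(list(frame["subject"]), "subject id")
        times = frame["time"].to_numpy(dtype=float)
        bad = ~np.isfinite(times) | (times <= 0)
        if bad.any():
            i = int(np.argmax(bad))
            raise ValidationError(
                f"time must be finite and > 0; got {times[i]} for subject "
                f"{frame['subject'].iloc[i]!r}"
            )
        frame["time"] = times
        frame["event"] = frame["event"].astype(bool)
        self.frame = frame
        self.metadata = dict(metadata or {})

    @property
    def groups(self) -> list:
        return list(pd.unique(self.frame["group"]))

    def subset(self, group) -> pd.DataFrame:
        sub = self.frame[self.frame["group"] == group]
        if sub.empty:
            raise ValidationError(f"no subjects in group {group!r}")
        return sub

    def __len__(self):
        return len(self.frame)


class StiffnessExpressionTable(_FrameBacked):
    """Per-well analyte concentrations with substratum stiffness.

    Columns: ``well`` (id), ``stiffness_kpa`` (> 0), ``analyte``,
    ``concentration`` (pg/mL, >= 0), ``cell_factor`` (cell-number
    normalization factor, > 0, default 1).
    """

    REQUIRED = ("well", "stiffness_kpa", "analyte", "concentration", "cell_factor")

    def __init__(self, frame: pd.DataFrame, metadata: dict | None = None):
        frame = frame.copy().reset_index(drop=True)
        if "cell_factor" not in frame.columns:
            frame["cell_factor"] = 1.0
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValidationError(f"stiffness table missing columns {missing}")
        frame = frame[list(self.REQUIRED)]
        for col, lo, strict in (("stiffness_kpa", 0.0, True),
                                ("concentration", 0.0, False),
                                ("cell_factor", 0.0, True)):
            v = frame[col].to_numpy(dtype=float)
            bad = ~np.isfinite(v) | ((v <= lo) if strict else (v < lo))
            if bad.any():
                i = int(np.argmax(bad))
                op = ">" if strict else ">="
                raise ValidationError(
                    f"{col} must be {op} {lo}; got {v[i]} in row {i} "
                    f"(well {frame['well'].iloc[i]!r})"
                )
            frame[col] = v
        self.frame = frame
        self.metadata = dict(metadata or {})

    @property
    def analytes(self) -> list:
        return list(pd.unique(self.frame["analyte"]))

    @property
    def stiffness_levels(self) -> np.ndarray:
        return np.sort(pd.unique(self.frame["stiffness_kpa"]))
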