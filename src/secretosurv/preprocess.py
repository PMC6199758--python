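"""Preprocessing of multiplex/ELISA concentration readouts.

Three steps turn raw per-well readouts into the modelling table: technical
replicates are collapsed to their arithmetic mean, concentrations are
rescaled by per-group cell-number normalization factors, and analytes that
never rise above their assay detection limit are removed (or imputed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import AnalytePanel, ExpressionMatrix, ValidationError

__all__ = [
    "collapse_technical_replicates",
    "normalize_by_cell_count",
    "apply_lod_policy",
    "LOD_POLICIES",
]

LOD_POLICIES = ("drop_if_all_below", "substitute_half_lod", "keep")


def collapse_technical_replicates(wells: pd.DataFrame,
                                  panel: AnalytePanel | None = None,
                                  ) -> ExpressionMatrix:
    """Average technical replicates into one concentration per (group, analyte).

    Parameters
    ----------
    wells : DataFrame
        Long-format readouts with columns ``group``, ``analyte``,
        ``concentration``; one row per replicate well.
    panel : AnalytePanel, optional
        If given, every (group, analyte) pair over the full panel must be
        present and the output columns follow panel order.

    Returns
    -------
    ExpressionMatrix
        Cell value = arithmetic mean of the replicates; per-cell replicate
        counts are recorded in ``metadata["replicate_counts"]``.
    """
    need = {"group", "analyte", "concentration"}
    missing = need - set(wells.columns)
    if missing:
        raise ValidationError(f"replicate table missing columns {sorted(missing)}")
    groups = list(pd.unique(wells["group"]))
    analytes = (list(panel.analyte_names) if panel is not None
                else list(pd.unique(wells["analyte"])))
    grouped = wells.groupby(["group", "analyte"])["concentration"]
    means = grouped.mean()
    counts = grouped.size()
    absent = [(g, a) for g in groups for a in analytes if (g, a) not in means.index]
    if absent:
        raise ValidationError(f"missing replicate(s) for (group, analyte) pairs: {absent}")
    frame = pd.DataFrame(
        [[means[(g, a)] for a in analytes] for g in groups],
        index=groups, columns=analytes)
    counts_frame = pd.DataFrame(
        [[int(counts[(g, a)]) for a in analytes] for g in groups],
        index=groups, columns=analytes)
    return ExpressionMatrix(
        frame, panel=panel,
        metadata={"replicate_counts": counts_frame.to_dict(),
                  "processing": ["collapse_technical_replicates"]})


def normalize_by_cell_count(matrix: ExpressionMatrix, factors) -> ExpressionMatrix:
    """Multiply each group's row by its cell-number normalization factor.

    Factors correct for unequal cell numbers across culture conditions; a
    factor of 1 leaves a group unchanged.  All factors must be positive and
    one must be supplied per group.
    """
    missing = [g for g in matrix.groups if g not in factors]
    if missing:
        raise ValidationError(f"no normalization factor for group(s) {missing}")
    for g in matrix.groups:
        f = float(factors[g])
        if not np.isfinite(f) or f <= 0:
            raise ValidationError(f"normalization factor for group {g!r} must be > 0, got {f}")
    scaled = matrix.frame.mul(
        pd.Series({g: float(factors[g]) for g in matrix.groups}), axis=0)
    meta = dict(matrix.metadata)
    meta.setdefault("processing", []).append("normalize_by_cell_count")
    meta["cell_count_factors"] = {str(g): float(factors[g]) for g in matrix.groups}
    return ExpressionMatrix(scaled, panel=matrix.panel, metadata=meta)


def apply_lod_policy(matrix: ExpressionMatrix, panel: AnalytePanel,
                     policy: str = "drop_if_all_below"):
    """Handle analytes at or below the assay's limit of detection.

    Policies
    --------
    ``drop_if_all_below`` (default)
        Remove an analyte only when *every* sample is below its LOD (the
        whole analyte is then uninformative), and report the removals.
    ``substitute_half_lod``
        Replace individual below-LOD cells with LOD/2.
    ``keep``
        No change.

    Returns
    -------
    (ExpressionMatrix, list of str)
        The processed matrix and the dropped analyte names (empty unless
        the default policy removed anything).
    """
    if policy not in LOD_POLICIES:
        raise ValidationError(f"unknown LOD policy {policy!r}; choose from {LOD_POLICIES}")
    meta = dict(matrix.metadata)
    meta.setdefault("processing", []).append(f"apply_lod_policy[{policy}]")
    if policy == "keep":
        return ExpressionMatrix(matrix.frame, panel=matrix.panel, metadata=meta), []
    if panel.lod is None:
        raise ValidationError(f"policy {policy!r} requires per-analyte LODs on the panel")
    frame = matrix.frame.copy()
    dropped: list = []
    for analyte in list(frame.columns):
        lod = panel.lod.get(analyte)
        if lod is None:
            continue
        below = frame[analyte].to_numpy() < lod
        if policy == "drop_if_all_below":
            if below.all():
                dropped.append(analyte)
        else:  # substitute_half_lod
            frame.loc[below, analyte] = lod / 2.0
    if dropped:
        frame = frame.drop(columns=dropped)
        meta["dropped_below_lod"] = list(dropped)
    # the panel no longer matches once columns were dropped
    out_panel = matrix.panel if not dropped else None
    return ExpressionMatrix(frame, panel=out_panel, metadata=meta), dropped
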