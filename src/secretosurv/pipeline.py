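"""Config-driven orchestration: simulate -> screen -> fit -> predict -> validate.

A :class:`PipelineConfig` either points at input CSVs or describes a
simulation; :func:`run_pipeline` executes the stages in order, writes every
intermediate table under the output directory, and returns a
:class:`RunReport` that is byte-reproducible from config + seed.  Any stage
error aborts the run with the stage name and offending input; partial
outputs are retained next to a ``FAILED`` marker.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as sio
from .datamodel import ValidationError
from .pls import (
    SecretomeSurvivalPLS,
    consensus_biomarkers,
    loading_map,
    rank_biomarkers_by_proximity,
    save_model,
    variance_explained,
)
from .screen import timepoint_screen
from .simulate import EventSimConfig, generate_event_tables, generate_secretome_survival
from .survival import km_estimate, logrank_test, median_survival, mh_hazard_ratio

__all__ = ["PipelineConfig", "RunReport", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    """Everything a run needs; file paths win over simulation parameters."""

    seed: int = 1
    output_dir: str = "secretosurv_run"

    # inputs: either paths ...
    expression_path: str | None = None
    survival_path: str | None = None
    events_path: str | None = None
    # ... or simulation parameters
    n_groups: int = 5
    n_analytes: int = 35
    n_timepoints: int = 21
    n_informative: int = 8
    noise_sd: float = 0.05
    latent_rank: int = 1
    event_hazards: dict | None = None   # cohort label -> deaths/day
    n_per_group: int = 9
    censor_time: float = 50.0

    # screen thresholds
    rho_threshold: float = 0.875
    alpha: float = 0.05
    aggregation: str = "majority"

    # PLSR settings
    n_components: int = 2
    algorithm: str = "simpls"
    clip: bool = True
    monotone: bool = False
    proximity_metric: str = "cosine"
    top_k: int | None = None            # default: Pearson hit-list size

    # survival comparisons
    group_a: str | None = None
    group_b: str | None = None
    hr_method: str = "mantel-haenszel"

    def __post_init__(self):
        if not 0 <= self.rho_threshold <= 1:
            raise ValidationError("rho_threshold must be in [0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        obj = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**obj)

    def stage_seed(self, k: int) -> int:
        """Deterministic per-stage substream seed derived from the run seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(k,))
        return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run (no timestamps)."""

    config: dict
    seed: int
    stages: dict = field(default_factory=dict)
    pearson_hits: list = field(default_factory=list)
    plsr_top: list = field(default_factory=list)
    consensus: list = field(default_factory=list)
    model_path: str | None = None
    prediction_path: str | None = None
    parity_slope: float | None = None
    statistics: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n",
            encoding="utf-8")

    def text(self) -> str:
        lines = [f"secretosurv run (seed {self.seed})"]
        for stage, rec in self.stages.items():
            lines.append(f"  [{stage}] " + ", ".join(
                f"{k}={v}" for k, v in rec.items()))
        lines.append(f"  Pearson hits ({len(self.pearson_hits)}): "
                     f"{', '.join(self.pearson_hits) or '-'}")
        lines.append(f"  consensus ({len(self.consensus)}): "
                     f"{', '.join(self.consensus) or '-'}")
        if self.parity_slope is not None:
            lines.append(f"  parity slope (observed vs fitted): "
                         f"{self.parity_slope:.4f}")
        for name, rec in self.statistics.items():
            lines.append(f"  {name}: {json.dumps(rec, sort_keys=True)}")
        return "\n".join(lines)


def _log(msg: str) -> None:
    import sys
    print(f"secretosurv: {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config), seed=config.seed)
    stage = "inputs"
    try:
        # ---------------------------------------------------------- inputs
        if config.expression_path or config.survival_path:
            if not (config.expression_path and config.survival_path):
                raise PipelineError(
                    "inputs", "expression_path and survival_path must be "
                    "given together")
            if not Path(config.expression_path).exists():
                raise PipelineError(
                    "inputs", f"missing expression file {config.expression_path}")
            if not Path(config.survival_path).exists():
                raise PipelineError(
                    "inputs", f"missing survival file {config.survival_path}")
            expr = sio.read_expression_csv(config.expression_path)
            surv = sio.read_survival_csv(config.survival_path)
            truth = None
        else:
            expr, surv, truth = generate_secretome_survival(
                config.n_groups, config.n_analytes, config.n_timepoints,
                config.n_informative, config.noise_sd,
                seed=config.stage_seed(0), latent_rank=config.latent_rank)
            truth.to_json(out / "truth.json")
        sio.write_expression_csv(expr, out / "expression.csv")
        sio.write_survival_csv(surv, out / "survival.csv")
        report.stages["inputs"] = {
            "groups": expr.shape[0], "analytes": expr.shape[1],
            "timepoints": surv.shape[1],
            "source": "files" if truth is None else "simulated"}
        _log(f"inputs: {expr.shape[0]} groups x {expr.shape[1]} analytes, "
             f"{surv.shape[1]} timepoints")

        # ---------------------------------------------------------- screen
        stage = "screen"
        screen = timepoint_screen(expr, surv, config.rho_threshold,
                                  config.alpha, config.aggregation)
        screen.to_csv(out / "screen.csv")
        (out / "screen.json").write_text(
            json.dumps(screen.summary(), indent=1, sort_keys=True) + "\n",
            encoding="utf-8")
        report.pearson_hits = [str(h) for h in screen.hits]
        report.stages["screen"] = {
            "evaluable_cells": int(screen.table["evaluable"].sum()),
            "hits": len(screen.hits)}
        _log(f"screen: {len(screen.hits)} aggregate hits")

        # ------------------------------------------------------------- fit
        stage = "fit"
        model = SecretomeSurvivalPLS(
            n_components=config.n_components, algorithm=config.algorithm,
            clip=config.clip, monotone=config.monotone,
            proximity_metric=config.proximity_metric).fit(expr, surv)
        save_model(model, out / "model.json")
        variance_explained(model).to_csv(out / "variance_explained.csv",
                                         index=False)
        if config.n_components >= 2:
            loading_map(model).to_csv(out / "loading_map.csv")
            ranking = rank_biomarkers_by_proximity(model)
            ranking.to_csv(out / "biomarker_ranking.csv")
            k = config.top_k if config.top_k is not None \
                else max(len(screen.hits), 1)
            report.plsr_top = [str(a) for a in ranking.top(k)]
        report.model_path = str(out / "model.json")
        report.stages["fit"] = {
            "components": config.n_components,
            "x_var_cum": float(np.sum(model.x_variance_explained_)),
            "y_var_cum": float(np.sum(model.y_variance_explained_))}
        _log(f"fit: cumulative variance X={report.stages['fit']['x_var_cum']:.3f} "
             f"Y={report.stages['fit']['y_var_cum']:.3f}")

        # --------------------------------------------------------- predict
        stage = "predict"
        fitted = model.predict(expr)
        sio.write_survival_csv(fitted, out / "predicted_curves.csv")
        obs = surv.values.ravel()
        fit_v = fitted.values.ravel()
        slope = float(np.polyfit(obs, fit_v, 1)[0]) if obs.std() > 0 else None
        parity = np.column_stack([obs, fit_v])
        np.savetxt(out / "parity.csv", parity, delimiter=",",
                   header="observed,fitted", comments="")
        report.prediction_path = str(out / "predicted_curves.csv")
        report.parity_slope = slope
        report.stages["predict"] = {"cells": int(obs.size),
                                    "parity_slope": slope}
        _log(f"predict: parity slope {slope}")

        # ------------------------------------------------------- consensus
        stage = "consensus"
        cons = consensus_biomarkers(report.pearson_hits, report.plsr_top)
        report.consensus = [str(a) for a in cons.overlap]
        report.stages["consensus"] = {
            "n_pearson": cons.n_pearson, "n_plsr": cons.n_plsr,
            "n_overlap": cons.n_overlap}
        _log(f"consensus: {cons.n_overlap} overlapping biomarkers")

        # -------------------------------------------------------- survival
        stage = "survival"
        events = None
        if config.events_path:
            if not Path(config.events_path).exists():
                raise PipelineError(
                    "survival", f"missing events file {config.events_path}")
            events = sio.read_event_table_csv(config.events_path)
        elif config.event_hazards:
            events = generate_event_tables(EventSimConfig(
                group_hazards=config.event_hazards,
                n_per_group=config.n_per_group,
                censor_time=config.censor_time,
                seed=config.stage_seed(1)))
            sio.write_event_table_csv(events, out / "events.csv")
        if events is not None:
            stats_rec: dict = {}
            for g in events.groups:
                curve = km_estimate(events, g)
                med = median_survival(curve)
                stats_rec[f"km[{g}]"] = {
                    "n": curve.n_subjects,
                    "deaths": int(curve.deaths.sum()),
                    "endpoint_survival": curve.survival_at(curve.max_followup),
                    "median": med if med is not None else "undefined"}
            ga = config.group_a or events.groups[0]
            gb = config.group_b or events.groups[1]
            lr = logrank_test(events, ga, gb)
            hr = mh_hazard_ratio(events, ga, gb, method=config.hr_method)
            stats_rec[f"logrank[{ga} vs {gb}]"] = lr.as_record()
            stats_rec[f"hazard_ratio[{ga} vs {gb}]"] = hr.as_record()
            report.statistics = stats_rec
            report.stages["survival"] = {"groups": len(events.groups),
                                         "subjects": len(events)}
            _log(f"survival: {len(events)} subjects in {len(events.groups)} "
                 f"cohorts")
    except PipelineError:
        (out / "FAILED").write_text(f"stage {stage}\n", encoding="utf-8")
        raise
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n", encoding="utf-8")
        raise PipelineError(stage, str(exc)) from exc

    report.to_json(out / "report.json")
    (out / "report.txt").write_text(report.text() + "\n", encoding="utf-8")
    return report
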