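"""Synthetic potency-study generator.

The analysis assumes a specific statistical structure: each MSC preparation
carries a latent potency score that simultaneously (i) shifts the
concentrations of a subset of secreted analytes and (ii) lowers the hazard
of the animals that received it.  This module generates data with exactly
that structure -- expression matrices, survival-proportion curves,
subject-level event tables under proportional hazards, and stiffness-graded
well tables -- so that every downstream stage (screen, PLSR, survival
statistics) can be tested against a known ground truth.

The generative model for the default, single-latent-factor design:

* potency scores ``theta_g`` equally spaced on [0, 1] (a 5-group design
  then always spans the potency range; random scores are available);
* informative analyte ``j``: ``c_gj = a_j + b_j * theta_g + eps``,
  ``eps ~ N(0, (noise_sd * a_j)^2)``, truncated at 0 (concentrations are
  physical); uninformative analytes are potency-independent noise around
  ``a_j``;
* survival ``S_g(t) = exp(-exp(-beta * theta_g) * Lam(t))`` with a
  piecewise-linear baseline cumulative hazard ``Lam`` that is 0 during a
  lag phase (no deaths before ~day 8, mimicking radiation-injury kinetics)
  and rises linearly to ``total_hazard`` at the end of follow-up.

Higher-potency groups therefore have uniformly higher survival curves, and
group ordering by ``theta`` equals group ordering by ``S(t)`` at every
timepoint with positive cumulative hazard.

A two-latent-factor design (``latent_rank=2``) mixes three template curves
with per-group simplex weights; noise-free data from it are exactly rank 2
after column standardization, which a two-component PLSR fits exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from .datamodel import (
    EventTable,
    ExpressionMatrix,
    StiffnessExpressionTable,
    SurvivalCurveMatrix,
    ValidationError,
)

__all__ = [
    "SimulationTruth",
    "EventSimConfig",
    "generate_secretome_survival",
    "generate_event_tables",
    "generate_stiffness_expression",
    "baseline_cumulative_hazard",
]

#: Name of the pseudo-random generator backing all simulations.
RNG_NAME = "numpy.random.Generator(PCG64)"


def baseline_cumulative_hazard(timepoints, lag_days: float = 8.0,
                               total_hazard: float = 2.0) -> np.ndarray:
    """Piecewise-linear baseline cumulative hazard over a timepoint grid.

    Zero during the lag phase, then linear up to ``total_hazard`` at the
    last timepoint.
    """
    t = np.asarray(timepoints, dtype=float)
    end = t[-1]
    if end <= lag_days:
        raise ValidationError("follow-up must extend beyond the lag phase")
    return np.clip((t - lag_days) / (end - lag_days), 0.0, None) * total_hazard


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated secretome/survival dataset."""

    theta: np.ndarray                 # latent potency per group (n_groups,) or (n_groups, 2)
    informative: list                 # informative analyte names
    intercepts: np.ndarray            # a_j, pg/mL
    slopes: np.ndarray                # b_j (0 for uninformative analytes)
    noise_sd: float                   # relative noise (CV) on concentrations
    baseline_timepoints: np.ndarray   # grid of the cumulative hazard, days
    baseline_cum_hazard: np.ndarray   # Lam(t) on the grid, non-decreasing, Lam(0)=0
    beta: float                       # potency effect on log-hazard
    seed: int | None
    rng_name: str = RNG_NAME
    latent_rank: int = 1

    def __post_init__(self):
        if len(self.informative) == 0:
            raise ValidationError("informative analyte set is empty")
        lam = np.asarray(self.baseline_cum_hazard, dtype=float)
        if lam[0] != 0.0 or np.any(np.diff(lam) < 0):
            raise ValidationError("baseline cumulative hazard must be "
                                  "non-decreasing with Lam(0) = 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def to_json(self, path) -> None:
        obj = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in asdict(self).items()}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)


def generate_secretome_survival(n_groups: int = 5, n_analytes: int = 35,
                                n_timepoints: int = 21, n_informative: int = 8,
                                noise_sd: float = 0.05, seed: int | None = None,
                                *, random_theta: bool = False, beta: float = 2.0,
                                followup_days: float = 50.0, lag_days: float = 8.0,
                                total_hazard: float = 2.0, latent_rank: int = 1,
                                ):
    """Simulate a linked (expression, survival) dataset with known truth.

    Defaults emulate the study design the analysis targets: 5 MSC
    preparations, 35 assayed analytes of which 8 are informative, and 21
    survival timepoints over a 50-day follow-up.

    Returns
    -------
    (ExpressionMatrix, SurvivalCurveMatrix, SimulationTruth)
    """
    if n_groups < 3:
        raise ValidationError("need at least 3 groups")
    if not 1 <= n_informative <= n_analytes:
        raise ValidationError("need 1 <= n_informative <= n_analytes")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if n_timepoints < 2:
        raise ValidationError("need at least 2 timepoints")
    if latent_rank not in (1, 2):
        raise ValidationError("latent_rank must be 1 or 2")

    rng = np.random.default_rng(seed)
    groups = [f"prep{g + 1}" for g in range(n_groups)]
    analytes = [f"analyte{j + 1:02d}" for j in range(n_analytes)]
    informative = analytes[:n_informative]

    grid = np.linspace(0.0, followup_days, n_timepoints)
    lam = baseline_cumulative_hazard(grid, lag_days, total_hazard)

    intercepts = rng.uniform(50.0, 500.0, n_analytes)
    slopes = np.zeros(n_analytes)

    if latent_rank == 1:
        theta = (rng.uniform(0.0, 1.0, n_groups) if random_theta
                 else np.linspace(0.0, 1.0, n_groups))
        slopes[:n_informative] = rng.uniform(0.5, 1.5, n_informative) * \
            intercepts[:n_informative]
        signal = np.outer(theta, slopes)
        surv = np.exp(-np.exp(-beta * theta)[:, None] * lam[None, :])
    else:
        # Two latent axes: survival curves are simplex mixtures of three
        # template curves; expression is affine in the two mixing weights.
        w = rng.dirichlet(np.ones(3), size=n_groups)      # (n_groups, 3)
        templates = np.exp(-np.exp(-beta * np.array([1.0, 0.5, 0.0]))[:, None]
                           * lam[None, :])                # (3, n_timepoints)
        surv = np.clip(w @ templates, 0.0, 1.0)  # guard fp round-off at S=1
        uv = w[:, :2]                                     # latent coordinates
        theta = uv
        half = max(1, n_informative // 2)
        coef = np.zeros((n_analytes, 2))
        coef[:half, 0] = rng.uniform(0.5, 1.5, half) * intercepts[:half]
        coef[half:n_informative, 1] = rng.uniform(0.5, 1.5, n_informative - half) * \
            intercepts[half:n_informative]
        slopes[:n_informative] = np.linalg.norm(coef[:n_informative], axis=1)
        signal = uv @ coef.T

    conc = intercepts[None, :] + signal
    if noise_sd > 0:
        conc = conc + rng.normal(0.0, 1.0, conc.shape) * (noise_sd * intercepts[None, :])
    conc = np.clip(conc, 0.0, None)

    expr = ExpressionMatrix(
        pd.DataFrame(conc, index=groups, columns=analytes),
        metadata={"simulated": True, "seed": seed, "rng": RNG_NAME,
                  "noise_sd": noise_sd, "latent_rank": latent_rank})
    curves = SurvivalCurveMatrix(
        pd.DataFrame(surv, index=groups, columns=grid),
        metadata={"simulated": True, "seed": seed, "rng": RNG_NAME})
    truth = SimulationTruth(
        theta=np.asarray(theta), informative=list(informative),
        intercepts=intercepts, slopes=slopes, noise_sd=noise_sd,
        baseline_timepoints=grid, baseline_cum_hazard=lam, beta=beta,
        seed=seed, latent_rank=latent_rank)
    return expr, curves, truth


@dataclass
class EventSimConfig:
    """Design of a simulated multi-cohort time-to-event experiment.

    ``group_hazards`` maps cohort label to a constant death hazard per day;
    subjects die at Exponential(lambda_g) times and are administratively
    censored at ``censor_time`` (default 50 days, the study's follow-up).
    The true hazard ratio between two cohorts is the ratio of their rates.
    """

    group_hazards: dict
    n_per_group: int = 9
    censor_time: float = 50.0
    seed: int | None = None

    def __post_init__(self):
        if not self.group_hazards:
            raise ValidationError("group_hazards is empty")
        for g, lam in self.group_hazards.items():
            if not np.isfinite(lam) or lam <= 0:
                raise ValidationError(f"hazard for group {g!r} must be > 0, got {lam}")
        if int(self.n_per_group) < 1:
            raise ValidationError("n_per_group must be >= 1")
        if self.censor_time <= 0:
            raise ValidationError("censor_time must be > 0")


def generate_event_tables(config: EventSimConfig) -> EventTable:
    """Draw subject-level event records under the configured design."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for g, lam in config.group_hazards.items():
        death = rng.exponential(1.0 / lam, int(config.n_per_group))
        for i, t in enumerate(death):
            event = t <= config.censor_time
            rows.append({
                "subject": f"{g}_{i + 1:03d}", "group": g,
                "time": float(t) if event else float(config.censor_time),
                "event": bool(event),
            })
    return EventTable(pd.DataFrame(rows),
                      metadata={"simulated": True, "seed": config.seed,
                                "rng": RNG_NAME,
                                "censor_time": config.censor_time})


def generate_stiffness_expression(stiffness_levels=(1.0, 10.0, 100.0),
                                  reps_per_level: int = 4,
                                  trend_slopes=None, n_analytes: int = 45,
                                  noise_sd: float = 10.0,
                                  seed: int | None = None,
                                  ) -> StiffnessExpressionTable:
    """Simulate per-well concentrations across substratum stiffness levels.

    Concentration of analyte ``j`` in a well at stiffness ``s`` is
    ``intercept_j + slope_j * (-log10 s) + N(0, noise_sd)``, truncated at 0;
    a positive slope therefore means the analyte increases as the
    substratum softens.  Default slopes are 0 (the all-null table used for
    familywise-error checks).  Intercepts are drawn in [100, 500] pg/mL so
    truncation at 0 never binds at the default noise level.
    """
    levels = np.asarray(stiffness_levels, dtype=float)
    if levels.size < 2:
        raise ValidationError("need at least 2 stiffness levels")
    if np.any(levels <= 0):
        raise ValidationError("stiffness must be > 0 kPa")
    if reps_per_level < 1:
        raise ValidationError("reps_per_level must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if trend_slopes is None:
        slopes = np.zeros(n_analytes)
    else:
        slopes = np.asarray(trend_slopes, dtype=float)
        n_analytes = slopes.size
    intercepts = rng.uniform(100.0, 500.0, n_analytes)
    analytes = [f"analyte{j + 1:02d}" for j in range(n_analytes)]
    rows = []
    well = 0
    for s in levels:
        for _ in range(reps_per_level):
            well += 1
            noise = rng.normal(0.0, noise_sd, n_analytes) if noise_sd > 0 else 0.0
            conc = np.clip(intercepts + slopes * (-np.log10(s)) + noise, 0.0, None)
            for j, a in enumerate(analytes):
                rows.append({"well": f"well{well:03d}", "stiffness_kpa": s,
                             "analyte": a,
                             "concentration": float(np.atleast_1d(conc)[j]),
                             "cell_factor": 1.0})
    return StiffnessExpressionTable(
        pd.DataFrame(rows),
        metadata={"simulated": True, "seed": seed, "rng": RNG_NAME})
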