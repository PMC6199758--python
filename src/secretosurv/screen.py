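"""Correlation screens for secreted-factor biomarkers.

Two screens are implemented:

* :class:`TimepointCorrelationScreen` -- per-timepoint Pearson correlation
  of each analyte's concentration (across preparations) with the survival
  proportion at that timepoint.  An analyte is an aggregate hit when the
  joint criterion |rho| > rho* AND p < alpha holds at a chosen fraction of
  the *evaluable* timepoints (default: the majority).  Timepoints where
  survival does not vary across groups (e.g. everyone still alive early
  on) are excluded as non-evaluable rather than counted as rho = 0.

* :class:`StiffnessCorrelationScreen` -- Spearman rank correlation of each
  analyte's per-well concentration with substratum stiffness, Bonferroni-
  corrected across the analytes tested (hit iff p < alpha / m).

p-values use the exact t transform: t = rho * sqrt((n-2) / (1-rho^2)) on
n-2 degrees of freedom, two-sided (anti-correlation is admissible).  With
n = 5 preparations the two-sided critical |rho| at alpha = 0.05 is ~0.8783,
so the joint criterion (0.875, 0.05) is nearly a single constraint there;
both thresholds are still applied literally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datamodel import (
    ExpressionMatrix,
    StiffnessExpressionTable,
    SurvivalCurveMatrix,
    ValidationError,
)

__all__ = [
    "CorrelationResult", "pearson_rho", "spearman_rho",
    "ScreenResult", "TimepointCorrelationScreen", "timepoint_screen",
    "StiffnessScreenResult", "StiffnessCorrelationScreen", "stiffness_screen",
]

_VAR_TOL = 1e-30  # squared-deviation threshold below which a vector is constant


class CorrelationResult(NamedTuple):
    rho: float
    p: float
    n: int
    evaluable: bool


def _t_pvalue(rho: float, n: int) -> float:
    # two-sided p from the exact t transform; |rho| -> 1 gives p -> 0
    r = min(1.0, max(-1.0, rho))
    if 1.0 - r * r <= 0.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def pearson_rho(x, y) -> CorrelationResult:
    """Sample Pearson correlation with a two-sided t-based p-value.

    Zero variance in either argument makes the coefficient undefined; the
    result is then flagged non-evaluable (rho and p are NaN) rather than
    raising, so screens can skip degenerate timepoints.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValidationError(f"need n >= 3 observations, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx < _VAR_TOL or syy < _VAR_TOL:
        return CorrelationResult(float("nan"), float("nan"), n, False)
    rho = float(np.clip((xc @ yc) / np.sqrt(sxx * syy), -1.0, 1.0))
    return CorrelationResult(rho, _t_pvalue(rho, n), n, True)


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties), t-approximate p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValidationError(f"need n >= 3 observations, got {x.size}")
    return pearson_rho(stats.rankdata(x), stats.rankdata(y))


def _pearson_columns(X: np.ndarray, y: np.ndarray):
    """Pearson rho of each column of X against y; NaN where undefined."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (Xc * Xc).sum(axis=0)
    syy = float(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (Xc.T @ yc) / np.sqrt(sxx * syy)
    rho = np.clip(rho, -1.0, 1.0)
    rho[sxx < _VAR_TOL] = np.nan
    if syy < _VAR_TOL:
        rho[:] = np.nan
    return rho


@dataclass
class ScreenResult:
    """Per-(analyte, timepoint) correlation statistics with aggregate flags."""

    table: pd.DataFrame          # analyte, timepoint, rho, p, n, evaluable, cell_hit
    per_analyte: pd.DataFrame    # analyte, n_evaluable, n_hit, frac_hit, hit
    rho_threshold: float
    alpha: float
    aggregation: str | float

    @property
    def hits(self) -> list:
        return list(self.per_analyte.loc[self.per_analyte["hit"], "analyte"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "rho_threshold": self.rho_threshold,
            "alpha": self.alpha,
            "aggregation": self.aggregation,
            "n_analytes": int(len(self.per_analyte)),
            "hits": self.hits,
        }


def _aggregate_fraction(aggregation) -> float:
    if aggregation == "majority":
        return 0.5
    if aggregation == "all":
        return 1.0
    if aggregation == "any":
        return np.nextafter(0.0, 1.0)
    frac = float(aggregation)
    if not 0.0 < frac <= 1.0:
        raise ValidationError(f"aggregation fraction must be in (0, 1], got {frac}")
    return frac


class TimepointCorrelationScreen(BaseEstimator):
    """Screen analytes for linear correlation with survival at every timepoint.

    Parameters
    ----------
    rho_threshold : float, default 0.875
        Minimum |rho| for a per-timepoint hit.
    alpha : float, default 0.05
        Two-sided significance level for a per-timepoint hit.
    aggregation : {"majority", "all", "any"} or float, default "majority"
        Fraction of evaluable timepoints at which the joint criterion must
        hold for an aggregate hit.

    Attributes (after ``fit``)
    --------------------------
    result_ : ScreenResult
    hits_ : list of analyte names flagged as aggregate hits
    """

    def __init__(self, rho_threshold: float = 0.875, alpha: float = 0.05,
                 aggregation="majority"):
        self.rho_threshold = rho_threshold
        self.alpha = alpha
        self.aggregation = aggregation

    def fit(self, X, y):
        expr = X.frame if isinstance(X, ExpressionMatrix) else pd.DataFrame(X)
        surv = y.frame if isinstance(y, SurvivalCurveMatrix) else pd.DataFrame(y)
        if set(expr.index) != set(surv.index):
            raise ValidationError(
                "expression and survival tables cover different groups: "
                f"{sorted(map(str, set(expr.index) ^ set(surv.index)))}")
        surv = surv.loc[expr.index]
        n = expr.shape[0]
        if n < 3:
            raise ValidationError(f"need at least 3 groups, got {n}")
        if not 0 < self.alpha <= 1:
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0 <= self.rho_threshold <= 1:
            raise ValidationError("rho_threshold must be in [0, 1]")
        frac_needed = _aggregate_fraction(self.aggregation)

        Xv = expr.to_numpy(dtype=float)
        rows = []
        for tp, yv in zip(surv.columns, surv.to_numpy(dtype=float).T):
            rho = _pearson_columns(Xv, yv)
            for j, analyte in enumerate(expr.columns):
                ev = bool(np.isfinite(rho[j]))
                p = _t_pvalue(rho[j], n) if ev else float("nan")
                hit = ev and abs(rho[j]) > self.rho_threshold and p < self.alpha
                rows.append((analyte, float(tp),
                             float(rho[j]) if ev else float("nan"),
                             p, n, ev, hit))
        table = pd.DataFrame(
            rows, columns=["analyte", "timepoint", "rho", "p", "n",
                           "evaluable", "cell_hit"])

        per = []
        for analyte, sub in table.groupby("analyte", sort=False):
            n_ev = int(sub["evaluable"].sum())
            n_hit = int(sub["cell_hit"].sum())
            frac = n_hit / n_ev if n_ev else 0.0
            per.append((analyte, n_ev, n_hit, frac,
                        n_ev > 0 and frac >= frac_needed))
        per_analyte = pd.DataFrame(
            per, columns=["analyte", "n_evaluable", "n_hit", "frac_hit", "hit"])
        if int(per_analyte["n_evaluable"].max()) == 0:
            warnings.warn("no evaluable timepoints: survival does not vary "
                          "across groups at any timepoint", stacklevel=2)
        self.result_ = ScreenResult(table, per_analyte, self.rho_threshold,
                                    self.alpha, self.aggregation)
        self.hits_ = self.result_.hits
        return self


def timepoint_screen(expr, surv, rho_threshold: float = 0.875,
                     alpha: float = 0.05, aggregation="majority") -> ScreenResult:
    """Functional wrapper around :class:`TimepointCorrelationScreen`."""
    return TimepointCorrelationScreen(rho_threshold, alpha, aggregation) \
        .fit(expr, surv).result_


_EXACT_PERM_LIMIT = 200_000   # max partitions to enumerate for exact p
_null_cache: dict = {}


def _exact_spearman_null(s_ranks: tuple, r_ranks: tuple) -> np.ndarray:
    """Exact permutation null of |rho| for a grouped rank design.

    When one variable takes only a few distinct values (stiffness levels),
    the Spearman statistic depends only on which ranks of the other
    variable land in which level group, so the full permutation
    distribution collapses to multinomial partitions and can be enumerated.
    Returns the sorted array of |rho| over all partitions, or None when the
    partition count exceeds the enumeration limit.
    """
    from itertools import combinations
    from math import comb

    # the null depends only on the two rank multisets, not their pairing
    key = (tuple(sorted(s_ranks)), tuple(sorted(r_ranks)))
    if key in _null_cache:
        return _null_cache[key]
    s = np.asarray(s_ranks, dtype=float)
    r = np.asarray(r_ranks, dtype=float)
    n = s.size
    levels, counts = np.unique(s, return_counts=True)
    total = 1
    rem = n
    for c in counts:
        total *= comb(rem, int(c))
        rem -= int(c)
    if total > _EXACT_PERM_LIMIT:
        _null_cache[key] = None
        return None
    sc = s - s.mean()
    denom = np.sqrt((sc @ sc) * ((r - r.mean()) @ (r - r.mean())))
    if denom < _VAR_TOL:
        _null_cache[key] = None
        return None
    level_dev = levels - s.mean()

    sums: list = []

    def recurse(pool: tuple, level_idx: int, acc: float):
        if level_idx == len(counts) - 1:
            sums.append(acc + level_dev[level_idx] * sum(pool))
            return
        c = int(counts[level_idx])
        for chosen in combinations(range(len(pool)), c):
            chosen_set = set(chosen)
            rest = tuple(v for i, v in enumerate(pool) if i not in chosen_set)
            part = sum(pool[i] for i in chosen)
            recurse(rest, level_idx + 1, acc + level_dev[level_idx] * part)

    recurse(tuple(r), 0, 0.0)
    null = np.sort(np.abs(np.asarray(sums) / denom))
    _null_cache[key] = null
    return null


@dataclass
class StiffnessScreenResult:
    """Per-analyte Spearman statistics against substratum stiffness."""

    table: pd.DataFrame      # analyte, rho, p, n, hit, direction
    alpha: float
    n_tested: int            # m, the Bonferroni divisor

    @property
    def adjusted_alpha(self) -> float:
        return self.alpha / self.n_tested

    @property
    def hits(self) -> list:
        return list(self.table.loc[self.table["hit"], "analyte"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


class StiffnessCorrelationScreen(BaseEstimator):
    """Spearman screen of analyte concentration against substratum stiffness.

    Wells are pooled; stiffness (kPa) enters as the rank covariate, so any
    strictly monotone coding of the levels gives identical results.  The
    per-analyte threshold is Bonferroni-corrected: hit iff p < alpha / m
    with m the number of analytes tested.

    Because stiffness takes only a few distinct levels, the default
    ``p_method="exact"`` enumerates the exact permutation null of the rank
    statistic (cached per design); the t approximation is anti-conservative
    in the far tail that Bonferroni probes at typical well counts, which
    would inflate the familywise error.  ``p_method="t-approx"`` selects
    the approximation; designs too large to enumerate fall back to it
    automatically.
    """

    def __init__(self, alpha: float = 0.05, p_method: str = "exact"):
        self.alpha = alpha
        self.p_method = p_method

    def fit(self, X, y=None):
        if not isinstance(X, StiffnessExpressionTable):
            raise ValidationError("fit expects a StiffnessExpressionTable")
        f = X.frame
        if len(X.stiffness_levels) < 2:
            raise ValidationError("stiffness is constant: need >= 2 levels")
        if self.p_method not in ("exact", "t-approx"):
            raise ValidationError(f"unknown p_method {self.p_method!r}")
        analytes = X.analytes
        m = len(analytes)
        rows = []
        for analyte in analytes:
            sub = f[f["analyte"] == analyte]
            if len(sub) < 3:
                raise ValidationError(
                    f"analyte {analyte!r} has fewer than 3 wells")
            conc = sub["concentration"].to_numpy() * sub["cell_factor"].to_numpy()
            res = spearman_rho(sub["stiffness_kpa"].to_numpy(), conc)
            if res.evaluable and self.p_method == "exact":
                s_ranks = tuple(stats.rankdata(sub["stiffness_kpa"]))
                r_ranks = tuple(stats.rankdata(conc))
                null = _exact_spearman_null(s_ranks, r_ranks)
                if null is not None:
                    count = null.size - np.searchsorted(
                        null, abs(res.rho) - 1e-12, side="left")
                    res = res._replace(p=float(count / null.size))
            hit = res.evaluable and res.p < self.alpha / m
            direction = ("increases_with_stiffness" if res.evaluable and res.rho > 0
                         else "decreases_with_stiffness" if res.evaluable
                         else "undefined")
            rows.append((analyte, res.rho, res.p, res.n, hit, direction))
        self.result_ = StiffnessScreenResult(
            pd.DataFrame(rows, columns=["analyte", "rho", "p", "n", "hit",
                                        "direction"]),
            alpha=self.alpha, n_tested=m)
        self.hits_ = self.result_.hits
        return self


def stiffness_screen(table: StiffnessExpressionTable,
                     alpha: float = 0.05) -> StiffnessScreenResult:
    """Functional wrapper around :class:`StiffnessCorrelationScreen`."""
    return StiffnessCorrelationScreen(alpha).fit(table).result_
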