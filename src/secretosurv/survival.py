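"""Survival statistics for cohort validation.

Kaplan-Meier product-limit estimation, median survival, the two-group
Mantel-Cox (log-rank) test, the Mantel-Haenszel hazard ratio, one-tailed
Welch t tests, and familywise p-value adjustment.  All statistics are
computed from first principles on :class:`~secretosurv.datamodel.EventTable`
records; tied death times are pooled into one stratum with the
hypergeometric variance, and subjects censored at a death time leave the
risk set after the deaths are counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .datamodel import EventTable, ValidationError

__all__ = [
    "KMCurve", "km_estimate", "median_survival",
    "LogRankResult", "logrank_test",
    "HazardRatioResult", "mh_hazard_ratio",
    "WelchResult", "welch_t_test",
    "adjust_pvalues",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate for one cohort."""

    group: object
    death_times: np.ndarray   # distinct death times, increasing
    survival: np.ndarray      # S(t) just after each death time
    at_risk: np.ndarray       # risk-set size just before each death time
    deaths: np.ndarray        # deaths at each death time
    n_subjects: int
    max_followup: float       # largest observed time (death or censoring)

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S = 1 before the first death."""
        idx = np.searchsorted(self.death_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_estimate(events: EventTable, group) -> KMCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Censored subjects leave the risk set just after their censoring time,
    so they still count as at-risk for deaths occurring at that same time.
    """
    sub = events.subset(group)
    times = sub["time"].to_numpy(dtype=float)
    died = sub["event"].to_numpy(dtype=bool)
    death_times = np.unique(times[died])
    surv, at_risk, deaths = [], [], []
    s = 1.0
    for t in death_times:
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum((times == t) & died))
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        deaths.append(d_i)
        surv.append(s)
    return KMCurve(group=group, death_times=death_times,
                   survival=np.asarray(surv), at_risk=np.asarray(at_risk),
                   deaths=np.asarray(deaths), n_subjects=len(sub),
                   max_followup=float(times.max()))


def median_survival(curve: KMCurve) -> float | None:
    """Smallest death time with S(t) <= 0.5; None when never reached.

    ``None`` corresponds to a median reported as "undefined (> follow-up)".
    """
    reached = curve.survival <= 0.5
    if not reached.any():
        return None
    return float(curve.death_times[int(np.argmax(reached))])


def _two_group_oev(events: EventTable, group_a, group_b):
    """Summed observed/expected deaths in A and hypergeometric variance."""
    sub_a = events.subset(group_a)
    sub_b = events.subset(group_b)
    ta = sub_a["time"].to_numpy(dtype=float)
    tb = sub_b["time"].to_numpy(dtype=float)
    da = sub_a["event"].to_numpy(dtype=bool)
    db = sub_b["event"].to_numpy(dtype=bool)
    death_times = np.unique(np.concatenate([ta[da], tb[db]]))
    if death_times.size == 0:
        raise ValidationError("test undefined: no deaths in either group")
    O = E = V = 0.0
    for t in death_times:
        n_a = int(np.sum(ta >= t))
        n_b = int(np.sum(tb >= t))
        d_a = int(np.sum((ta == t) & da))
        d_b = int(np.sum((tb == t) & db))
        n = n_a + n_b
        d = d_a + d_b
        O += d_a
        E += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    totals = {"observed_a": O, "observed_b": float(da.sum() + db.sum()) - O,
              "expected_a": E,
              "expected_b": float(da.sum() + db.sum()) - E}
    return O, E, V, totals


@dataclass
class LogRankResult:
    """Mantel-Cox log-rank comparison of two cohorts (1 df)."""

    statistic: float
    p: float
    observed: dict       # per-group observed deaths
    expected: dict       # per-group expected deaths
    variance: float
    groups: tuple

    def as_record(self) -> dict:
        return {"statistic": self.statistic, "p": self.p, "df": 1,
                "O": self.observed, "E": self.expected, "V": self.variance,
                "method": "logrank"}


def logrank_test(events: EventTable, group_a, group_b) -> LogRankResult:
    """Two-group log-rank test: chi2 = (O_A - E_A)^2 / V on 1 df."""
    O, E, V, tot = _two_group_oev(events, group_a, group_b)
    if V <= 0:
        raise ValidationError("test undefined: zero variance "
                              "(no death time with both groups at risk)")
    chi2 = (O - E) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(
        statistic=float(chi2), p=p,
        observed={str(group_a): tot["observed_a"], str(group_b): tot["observed_b"]},
        expected={str(group_a): tot["expected_a"], str(group_b): tot["expected_b"]},
        variance=float(V), groups=(group_a, group_b))


@dataclass
class HazardRatioResult:
    """Hazard of group A relative to group B (the reference)."""

    hr: float
    ci: tuple
    method: str
    reference: object
    groups: tuple

    def as_record(self) -> dict:
        return {"HR": self.hr, "CI": list(self.ci), "method": self.method,
                "reference": str(self.reference)}


def mh_hazard_ratio(events: EventTable, group_a, group_b,
                    method: str = "mantel-haenszel") -> HazardRatioResult:
    """Hazard ratio of A vs B from the log-rank risk tables.

    ``mantel-haenszel`` (default): HR = exp((O_A - E_A) / V), 95% CI
    exp((O_A - E_A)/V +/- 1.96/sqrt(V)).  ``logrank-OE``:
    HR = (O_A / E_A) / (O_B / E_B), CI on the log scale with variance
    1/E_A + 1/E_B.
    """
    if method not in ("mantel-haenszel", "logrank-OE"):
        raise ValidationError(f"unknown hazard-ratio method {method!r}")
    O, E, V, tot = _two_group_oev(events, group_a, group_b)
    if V <= 0:
        raise ValidationError("hazard ratio undefined: zero variance")
    z = stats.norm.ppf(0.975)
    if method == "mantel-haenszel":
        log_hr = (O - E) / V
        half = z / np.sqrt(V)
    else:
        if tot["expected_a"] <= 0 or tot["expected_b"] <= 0 \
                or tot["observed_a"] <= 0 or tot["observed_b"] <= 0:
            raise ValidationError("logrank-OE undefined with zero "
                                  "observed/expected deaths")
        log_hr = np.log((tot["observed_a"] / tot["expected_a"]) /
                        (tot["observed_b"] / tot["expected_b"]))
        half = z * np.sqrt(1.0 / tot["expected_a"] + 1.0 / tot["expected_b"])
    return HazardRatioResult(
        hr=float(np.exp(log_hr)),
        ci=(float(np.exp(log_hr - half)), float(np.exp(log_hr + half))),
        method=method, reference=group_b, groups=(group_a, group_b))


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_t_test(a, b, tail: str = "two_sided") -> WelchResult:
    """Student's t test with unequal variances (Satterthwaite df).

    ``tail`` is one of ``one_sided_greater`` (H1: mean(a) > mean(b)),
    ``one_sided_less``, or ``two_sided``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("samples must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        raise ValidationError("both samples are constant and equal")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    if tail == "two_sided":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif tail == "one_sided_greater":
        p = stats.t.sf(t, df)
    elif tail == "one_sided_less":
        p = stats.t.cdf(t, df)
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return WelchResult(float(t), float(df), float(p))


def adjust_pvalues(p, method: str = "holm") -> np.ndarray:
    """Familywise p-value adjustment.

    ``bonferroni``: min(1, m * p).  ``holm``: step-down Bonferroni with
    monotonicity enforcement (uniformly no larger than bonferroni).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        i = int(np.argmax((p < 0) | (p > 1) | ~np.isfinite(p)))
        raise ValidationError(f"p-value out of [0, 1] at position {i}: {p[i]}")
    m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method != "holm":
        raise ValidationError(f"unknown adjustment method {method!r}")
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
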