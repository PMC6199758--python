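import numpy as np
import pandas as pd
import pytest

from secretosurv import EventTable, ExpressionMatrix, SurvivalCurveMatrix


@pytest.fixture
def expr5x6():
    rng = np.random.default_rng(101)
    frame = pd.DataFrame(rng.uniform(10, 400, (5, 6)),
                         index=[f"g{i}" for i in range(5)],
                         columns=[f"a{j}" for j in range(6)])
    return ExpressionMatrix(frame)


@pytest.fixture
def surv5x5():
    t = [0.0, 10.0, 20.0, 30.0, 50.0]
    vals = np.array([
        [1.0, 0.9, 0.8, 0.7, 0.6],
        [1.0, 1.0, 0.9, 0.8, 0.8],
        [1.0, 0.8, 0.5, 0.3, 0.2],
        [1.0, 0.9, 0.9, 0.9, 0.9],
        [1.0, 0.7, 0.6, 0.4, 0.1],
    ])
    return SurvivalCurveMatrix(pd.DataFrame(
        vals, index=[f"g{i}" for i in range(5)], columns=t))


@pytest.fixture
def dhi_cohort():
    """9 subjects: deaths at days 10, 13, 16, 20; 5 censored at day 50."""
    rows = [dict(subject=f"d{i}", group="dhi", time=float(t), event=True)
            for i, t in enumerate([10, 13, 16, 20])]
    rows += [dict(subject=f"c{i}", group="dhi", time=50.0, event=False)
             for i in range(5)]
    return EventTable(pd.DataFrame(rows))


@pytest.fixture
def all_death_cohort():
    """9 subjects all dying; ordered death days 9..18 (5th death on day 13)."""
    rows = [dict(subject=f"s{i}", group="none", time=float(t), event=True)
            for i, t in enumerate([9, 10, 11, 12, 13, 15, 16, 17, 18])]
    return EventTable(pd.DataFrame(rows))


def random_event_table(rng, n_a=20, n_b=20, lam_a=0.05, lam_b=0.02,
                       censor=50.0) -> EventTable:
    rows = []
    for g, lam, n in (("A", lam_a, n_a), ("B", lam_b, n_b)):
        t = rng.exponential(1 / lam, n)
        for i, ti in enumerate(t):
            rows.append(dict(subject=f"{g}{i}", group=g,
                             time=min(float(ti), censor),
                             event=bool(ti <= censor)))
    return EventTable(pd.DataFrame(rows))
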