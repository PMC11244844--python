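"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import protosim as ps


@pytest.fixture(scope="session")
def a1_small():
    """Main setting scaled to a desk-size base population."""
    return ps.get_builtin_setting("A1").replace(
        setting_id="A1-small", base_population=300_000
    )


@pytest.fixture(scope="session")
def small_population(a1_small):
    return ps.simulate_population(a1_small, seed=424242)


# ---------------------------------------------------------------------------
# Independent Cox oracles
# ---------------------------------------------------------------------------

def brute_force_partial_loglik(rows: pd.DataFrame, beta: float) -> float:
    """Breslow partial log-likelihood evaluated by explicit risk-set loops.

    Deliberately naive (O(events x rows)) and independent of the
    package's sufficient-statistic computation.
    """
    start = rows["start"].to_numpy(float)
    stop = rows["stop"].to_numpy(float)
    exposed = rows["exposed"].to_numpy(int)
    event = rows["event"].to_numpy(int)
    ll = 0.0
    for t in np.unique(stop[event == 1]):
        cases = (event == 1) & (stop == t)
        at_risk = (start < t) & (t <= stop)
        risk_terms = np.exp(beta * exposed[at_risk])
        ll += beta * exposed[cases].sum() - cases.sum() * np.log(risk_terms.sum())
    return ll


def grid_maximize_loglik(rows: pd.DataFrame, lo: float = -5.0, hi: float = 5.0) -> float:
    """Maximise the brute-force partial likelihood over a log-HR interval."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda b: -brute_force_partial_loglik(rows, b),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def random_counting_dataset(rng: np.random.Generator, max_patients: int = 20) -> pd.DataFrame:
    """A random small start/stop dataset with events on both exposure arms.

    Guarantees exposure variation and at least one event per arm so the
    partial likelihood has an interior maximum.
    """
    while True:
        n = rng.integers(6, max_patients + 1)
        records = []
        for i in range(n):
            entry = rng.exponential(1.0)
            exit_ = entry + rng.exponential(2.0) + 1e-3
            event = int(rng.random() < 0.5)
            path = rng.integers(0, 3)  # 0: never exposed, 1: always, 2: switch
            if path == 2 and exit_ - entry > 0.1:
                switch = rng.uniform(entry, exit_)
                records.append((i, entry, switch, 0, 0))
                records.append((i, switch, exit_, 1, event))
            else:
                records.append((i, entry, exit_, int(path == 1), event))
        df = pd.DataFrame(records, columns=["id", "start", "stop", "exposed", "event"])
        ev = df[df.event == 1]
        if len(ev) >= 2 and ev.exposed.nunique() == 2:
            return df
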