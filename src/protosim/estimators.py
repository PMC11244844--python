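"""Survival estimators on counting-process data.

The analysis model is a Cox proportional-hazards regression with a
single binary, time-dependent covariate (ever-use of the second-line
treatment) on left-truncated (start, stop] intervals, plus
exposure-specific incidence rates with person-year denominators (the
closed-form maximiser of a Poisson model with a log person-time offset).

Because the covariate is binary, the partial likelihood depends on the
data only through per-event-time risk-set counts, which are computed
once with sorted searches; the Newton iteration itself is scalar.  Ties
are handled with the Breslow approximation (event times are continuous
here, so ties have probability zero and the choice is immaterial).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxFit",
    "IncidenceEstimate",
    "DegenerateDataError",
    "fit_cox_td",
    "estimate_incidence",
    "wald_significance",
]

#: Labels of the two exposure groups in the counting-process layout.
GROUP_LABELS = {0: "tcs", 1: "tacrolimus"}


class DegenerateDataError(ValueError):
    """Counting-process data cannot identify the hazard ratio at all."""


@dataclass(frozen=True)
class CoxFit:
    """Result of the one-covariate time-dependent Cox fit."""

    log_hr: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int
    converged: bool
    iterations: int


@dataclass(frozen=True)
class IncidenceEstimate:
    """Exposure-specific incidence: events per 1,000 person-years."""

    group: str
    events: int
    person_years: float
    rate: float


def _risk_set_counts(start, stop, exposed, event):
    """Per unique event time: (times, d0, d1, n0, n1).

    ``n_g(t)`` counts intervals of exposure group ``g`` at risk at time
    ``t`` (``start < t <= stop``); ``d_g(t)`` counts events at ``t`` in
    group ``g``.
    """
    ev_mask = event == 1
    ev_times = stop[ev_mask]
    ev_exposed = exposed[ev_mask]
    times = np.unique(ev_times)
    d1 = np.zeros(times.size)
    d0 = np.zeros(times.size)
    pos = np.searchsorted(times, ev_times)
    np.add.at(d1, pos, ev_exposed)
    np.add.at(d0, pos, 1 - ev_exposed)

    counts = []
    for g in (0, 1):
        m = exposed == g
        starts_g = np.sort(start[m])
        stops_g = np.sort(stop[m])
        counts.append(
            np.searchsorted(starts_g, times, side="left")
            - np.searchsorted(stops_g, times, side="left")
        )
    n0, n1 = counts
    return times, d0, d1, n0.astype(float), n1.astype(float)


def fit_cox_td(
    rows: pd.DataFrame,
    alpha: float = 0.05,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> CoxFit:
    """Maximise the Breslow partial likelihood by Newton iteration.

    ``rows`` uses the (id, start, stop, exposed, event) layout with
    half-open at-risk intervals (start, stop]; delayed entry is respected
    through the interval starts.  The score is iterated to absolute
    tolerance ``tol``; the standard error comes from the observed
    information at the optimum.

    Raises :class:`DegenerateDataError` when there is no event or no
    variation in exposure.  A monotone partial likelihood (all events on
    one exposure arm with one-sided risk sets) is reported as a
    non-converged fit rather than an exception.
    """
    start = rows["start"].to_numpy(float)
    stop = rows["stop"].to_numpy(float)
    exposed = rows["exposed"].to_numpy(np.int64)
    event = rows["event"].to_numpy(np.int64)
    if np.any(start >= stop):
        raise ValueError("every interval must satisfy start < stop")

    n_events = int(event.sum())
    if n_events == 0:
        raise DegenerateDataError("no events in the data")
    if exposed.min() == exposed.max():
        raise DegenerateDataError("exposure has no variation")

    _, d0, d1, n0, n1 = _risk_set_counts(start, stop, exposed, event)
    d_tot = d0 + d1
    s1 = float(d1.sum())  # total exposed events (sufficient statistic)

    beta = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eb = np.exp(beta)
        denom = n0 + n1 * eb
        pi = n1 * eb / denom
        score = s1 - float(np.sum(d_tot * pi))
        info = float(np.sum(d_tot * pi * (1.0 - pi)))
        if info <= 0.0 or not np.isfinite(score):
            break
        step = score / info
        beta += np.clip(step, -5.0, 5.0)
        if abs(beta) > 30.0:  # monotone likelihood: estimate diverges
            break
        if abs(score) < tol:
            converged = True
            break
    # a "solved" score at an absurd coefficient is saturation, not a maximum
    if abs(beta) > 15.0:
        converged = False

    eb = np.exp(beta)
    denom = n0 + n1 * eb
    pi = n1 * eb / denom
    info = float(np.sum(d_tot * pi * (1.0 - pi)))
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    p = 2.0 * stats.norm.sf(abs(beta) / se) if np.isfinite(se) and se > 0 else np.nan
    with np.errstate(over="ignore"):  # diverged fits: CI bounds saturate at inf
        return CoxFit(
            log_hr=beta,
            se=se,
            hr=float(np.exp(beta)),
            ci_low=float(np.exp(beta - z * se)),
            ci_high=float(np.exp(beta + z * se)),
            p_value=float(p) if np.isfinite(p) else np.nan,
            n_events=n_events,
            converged=converged,
            iterations=it,
        )


def cox_partial_loglik(rows: pd.DataFrame, log_hr: float) -> float:
    """Breslow partial log-likelihood at a given log hazard ratio.

    Exposed separately from the fitter so that tests can maximise it by
    brute force and cross-check the Newton solution.
    """
    start = rows["start"].to_numpy(float)
    stop = rows["stop"].to_numpy(float)
    exposed = rows["exposed"].to_numpy(np.int64)
    event = rows["event"].to_numpy(np.int64)
    _, d0, d1, n0, n1 = _risk_set_counts(start, stop, exposed, event)
    eb = np.exp(log_hr)
    return float(np.sum(d1 * log_hr - (d0 + d1) * np.log(n0 + n1 * eb)))


def estimate_incidence(rows: pd.DataFrame) -> dict[str, IncidenceEstimate]:
    """Events and person-years per exposure group, as rates per 1,000 p-y.

    The rate ``1000 * events / person_years`` is the maximum-likelihood
    estimate of a Poisson regression on the group indicator with a log
    person-time offset.  Groups with zero person-time are omitted with a
    warning.
    """
    out: dict[str, IncidenceEstimate] = {}
    py_len = rows["stop"].to_numpy(float) - rows["start"].to_numpy(float)
    exposed = rows["exposed"].to_numpy(np.int64)
    event = rows["event"].to_numpy(np.int64)
    for g, label in GROUP_LABELS.items():
        m = exposed == g
        py = float(py_len[m].sum())
        ev = int(event[m].sum())
        if py <= 0.0:
            warnings.warn(f"exposure group {label!r} has zero person-time; omitted")
            continue
        out[label] = IncidenceEstimate(
            group=label, events=ev, person_years=py, rate=1000.0 * ev / py
        )
    return out


def wald_significance(fit: CoxFit, alpha: float = 0.05) -> bool:
    """Two-sided Wald test of log HR = 0 at level ``alpha``."""
    if not fit.converged:
        raise ValueError("significance is undefined for a non-converged fit")
    return bool(fit.p_value < alpha)
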