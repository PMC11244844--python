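"""Cohort emulation: inclusion windows, left truncation and counting-process rows.

Mirrors a registry-based new-user design: each patient gets a random
administrative window of ``study_years`` starting at a uniformly drawn
inclusion age ``r0``; patients enter the cohort at their AD treatment
start (= AD diagnosis) or at ``r0``, whichever comes last, and exit at
the window end, death, or CTCL diagnosis, whichever comes first.  The
analysis timescale is time since treatment initiation, so patients whose
treatment started before ``r0`` enter late (left truncation).

Exposure follows the ever-use principle: person-time counts as
second-line (tacrolimus) from the first tacrolimus use onward and as
first-line (TCS) before it, with no return.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .latent import NEVER, LatentPopulation

__all__ = ["EmptyCohortError", "build_cohort", "assemble_cohort", "expand_counting_process"]

#: Column layout of a cohort table (one row per included patient).
COHORT_COLUMNS = ["id", "r0", "treat_start", "entry_age", "exit_age", "event", "switch_age"]

#: Column layout of the start/stop survival table.
COUNTING_COLUMNS = ["id", "start", "stop", "exposed", "event"]


class EmptyCohortError(RuntimeError):
    """No patient satisfied the inclusion criteria (pathological parameters)."""


def build_cohort(pop: LatentPopulation, params, seed: int) -> pd.DataFrame:
    """Draw inclusion ages and apply the study design to a population.

    ``r0`` is continuous uniform on ``[0, inclusion_age_max]``, drawn
    independently of all latent times.  Returns one row per included
    patient with columns ``id, r0, treat_start, entry_age, exit_age,
    event, switch_age``.
    """
    rng = np.random.default_rng(seed)
    r0 = rng.random(pop.n) * params.inclusion_age_max
    return assemble_cohort(pop, r0, params)


def assemble_cohort(pop: LatentPopulation, r0: np.ndarray, params) -> pd.DataFrame:
    """Deterministic part of :func:`build_cohort` given the inclusion ages.

    Inclusion requires strictly positive at-risk time: ``entry < exit``
    with ``entry = max(r0, treat_start)`` and ``exit = min(r0 +
    study_years, t_cens, t_ctcl_obs)``.  A CTCL diagnosis exactly at the
    window end or death age counts as an event (tie-break in favour of
    the event); a diagnosis exactly at entry contributes zero at-risk
    time and is excluded.
    """
    r0 = np.asarray(r0, dtype=float)
    if r0.shape != (pop.n,):
        raise ValueError("r0 must hold one inclusion age per patient")

    treat_start = pop.t_ad_obs
    # Restrict early to patients with any AD diagnosis: everyone else has
    # treat_start at the NEVER sentinel and can never enter.
    cand = np.flatnonzero(treat_start < NEVER)
    if cand.size == 0:
        raise EmptyCohortError("no patient was ever diagnosed with AD")

    r0_c = r0[cand]
    start_c = treat_start[cand]
    window_end = r0_c + params.study_years
    entry = np.maximum(r0_c, start_c)
    exit_age = np.minimum(np.minimum(window_end, pop.t_cens[cand]), pop.t_ctcl_obs[cand])
    included = entry < exit_age
    if not included.any():
        raise EmptyCohortError("inclusion criteria excluded every patient")

    idx = cand[included]
    event = pop.t_ctcl_obs[idx] <= exit_age[included]
    return pd.DataFrame(
        {
            "id": idx.astype(np.int64),
            "r0": r0[idx],
            "treat_start": treat_start[idx],
            "entry_age": entry[included],
            "exit_age": exit_age[included],
            "event": event.astype(np.int8),
            "switch_age": pop.t_tacro[idx],
        }
    )


def expand_counting_process(cohort: pd.DataFrame) -> pd.DataFrame:
    """Expand a cohort into (start, stop] rows on the treatment timescale.

    Time zero is treatment initiation (``treat_start``).  A switch to
    tacrolimus strictly inside the at-risk window splits the patient into
    an unexposed and an exposed row; a switch at or before entry makes
    the whole window exposed (ever-use history carries into the study);
    a switch at or after exit never surfaces in the data.
    """
    ids = cohort["id"].to_numpy(np.int64)
    start = cohort["entry_age"].to_numpy(float) - cohort["treat_start"].to_numpy(float)
    stop = cohort["exit_age"].to_numpy(float) - cohort["treat_start"].to_numpy(float)
    switch = cohort["switch_age"].to_numpy(float) - cohort["treat_start"].to_numpy(float)
    event = cohort["event"].to_numpy(np.int8)

    entry_age = cohort["entry_age"].to_numpy(float)
    exit_age = cohort["exit_age"].to_numpy(float)
    switch_age = cohort["switch_age"].to_numpy(float)

    split = (switch_age > entry_age) & (switch_age < exit_age)
    single = ~split
    exposed_single = (switch_age[single] <= entry_age[single]).astype(np.int8)

    out_id = np.concatenate([ids[single], ids[split], ids[split]])
    out_start = np.concatenate([start[single], start[split], switch[split]])
    out_stop = np.concatenate([stop[single], switch[split], stop[split]])
    out_exposed = np.concatenate(
        [
            exposed_single,
            np.zeros(split.sum(), dtype=np.int8),
            np.ones(split.sum(), dtype=np.int8),
        ]
    )
    out_event = np.concatenate(
        [event[single], np.zeros(split.sum(), dtype=np.int8), event[split]]
    )

    order = np.lexsort((out_start, out_id))
    return pd.DataFrame(
        {
            "id": out_id[order],
            "start": out_start[order],
            "stop": out_stop[order],
            "exposed": out_exposed[order],
            "event": out_event[order],
        }
    )
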