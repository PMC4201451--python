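"""Irreversible-endpoint detection and progression-path construction.

An EDSS level ``e`` is an *irreversible endpoint* for a patient when some
clinical visit records EDSS >= e and no later visit falls strictly below e
("progresses to a higher endpoint and never reverts to a lower endpoint").
Irreversibility is evaluated against all remaining follow-up, not a
confirmed-for-k-months window.

The attainment time of level ``e`` is the earliest visit from which the
record never again falls below ``e``.  Two boundary survival-time
assumptions bracket the unobserved true crossing time:

* **maximum** -- disability remains as last measured until the day of the
  next visit, so the event is placed on the attaining visit's day (slowest
  possible progression);
* **minimum** -- the event occurs on the day of a clinic visit but after
  it, represented numerically as the time of the last record strictly below
  the level before attainment (fastest possible progression).

The midpoint assumption lives in :mod:`edss_midpath.midpoint`.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from . import grid
from .records import (
    Assumption,
    EndpointEvent,
    EventStatus,
    IrreversiblePath,
    ObservationLabel,
    PatientTrajectory,
    Source,
    VisitRecord,
)


def _clinical_arrays(traj: PatientTrajectory) -> tuple[np.ndarray, np.ndarray]:
    clin = traj.clinical_visits
    if not clin:
        raise ValueError(f"patient {traj.patient_id}: no clinical visits")
    times = np.array([v.time for v in clin])
    edss = np.array([v.edss for v in clin])
    return times, edss


def irreversible_levels(traj: PatientTrajectory) -> list[tuple[float, float]]:
    """All irreversible endpoint levels >= 1.0 with their attainment times.

    Returns ``[(level, t_attained), ...]`` for every grid level from 1.0 up
    to the highest irreversible level (which is always the last visit's
    EDSS value, since nothing follows it to contradict it).
    """
    times, edss = _clinical_arrays(traj)
    # suffix minimum: m[i] = min(edss[i:]); level e is held from visit i
    # onward iff m[i] >= e.  m is non-decreasing, so attainment is a search.
    m = np.minimum.accumulate(edss[::-1])[::-1]
    # EDSS 10 (death due to MS) never forms an analysis endpoint
    levels = grid.levels_up_to(min(edss[-1], 9.5))
    idx = np.searchsorted(m, levels, side="left")
    return [(float(lv), float(times[i])) for lv, i in zip(levels, idx)]


def label_observations(
    traj: PatientTrajectory,
) -> list[tuple[VisitRecord, ObservationLabel]]:
    """Label every record in the trajectory (labels are exhaustive).

    A clinical visit is transitory (``Ot``) iff some later clinical visit is
    strictly lower.  The remaining clinical visits form a non-decreasing
    sequence; maximal runs of equal value are plateaus labelled first
    (``Of``), intermediate (``Om``) and last repeat (``Or``); a plateau
    visited once is just ``Of``.
    """
    out: dict[int, ObservationLabel] = {}
    clin_idx = [i for i, v in enumerate(traj.visits) if v.source is Source.CLINICAL]
    edss = np.array([traj.visits[i].edss for i in clin_idx])
    n = len(edss)
    if n:
        # min over strictly later clinical visits (+inf for the last one)
        later_min = np.concatenate(
            (np.minimum.accumulate(edss[::-1])[::-1][1:], [np.inf])
        )
        transitory = later_min < edss
        stable = [k for k in range(n) if not transitory[k]]
        # plateau runs of equal value within the stable subsequence
        runs: list[list[int]] = []
        for k in stable:
            if runs and edss[runs[-1][-1]] == edss[k]:
                runs[-1].append(k)
            else:
                runs.append([k])
        for k in range(n):
            if transitory[k]:
                out[clin_idx[k]] = ObservationLabel.TRANSITORY
        for run in runs:
            out[clin_idx[run[0]]] = ObservationLabel.FIRST
            if len(run) > 1:
                out[clin_idx[run[-1]]] = ObservationLabel.LAST_REPEAT
                for k in run[1:-1]:
                    out[clin_idx[k]] = ObservationLabel.INTERMEDIATE
    labelled = []
    for i, v in enumerate(traj.visits):
        if v.source is Source.ONSET_ANCHOR:
            labelled.append((v, ObservationLabel.ONSET))
        elif v.source is Source.EXPECTED_MIDPOINT:
            labelled.append((v, ObservationLabel.EXPECTED))
        else:
            labelled.append((v, out[i]))
    return labelled


def _validate_endpoint_level(level: float) -> float:
    level = grid.validate(level)
    if level < 1.0:
        raise ValueError(f"endpoint level must be >= 1.0, got {level}")
    if level == 10.0:
        raise ValueError("EDSS 10 (death due to MS) is not an analysis endpoint")
    return level


def event_time(
    traj: PatientTrajectory,
    level: float,
    assumption: Assumption | str,
) -> EndpointEvent:
    """Event/censor time at ``level`` under the maximum or minimum assumption.

    If the level is never irreversibly reached the patient is right-censored
    at the last clinical observation time (under every assumption).
    """
    level = _validate_endpoint_level(level)
    assumption = Assumption.parse(assumption)
    if assumption is Assumption.MIDPOINT:
        raise ValueError(
            "midpoint event times come from edss_midpath.midpoint"
        )
    irr = dict(irreversible_levels(traj))
    if level not in irr:
        return EndpointEvent(
            traj.patient_id,
            level,
            assumption,
            traj.last_clinical_time,
            EventStatus.RIGHT_CENSORED,
        )
    t_att = irr[level]
    if assumption is Assumption.MAXIMUM:
        t = t_att
    else:
        t = _last_below(traj, level, t_att)
        if t is None:
            # no record below the level precedes attainment (onset unknown
            # and the first visit already at the level): degenerate bracket
            t = t_att
    return EndpointEvent(traj.patient_id, level, assumption, t, EventStatus.EVENT)


def _last_below(
    traj: PatientTrajectory, level: float, before: float
) -> Optional[float]:
    """Time of the last record (anchor or clinical) strictly below ``level``
    and strictly before time ``before``; None if there is none."""
    best = None
    for v in traj.visits:
        if v.source is Source.EXPECTED_MIDPOINT:
            continue
        if v.time >= before:
            break
        if v.edss < level:
            best = v.time
    return best


def build_path(
    traj: PatientTrajectory, assumption: Assumption | str
) -> IrreversiblePath:
    """The (time, level) progression path through all irreversible levels."""
    assumption = Assumption.parse(assumption)
    steps: list[tuple[float, float]] = []
    if traj.anchor is not None or traj.onset_known:
        steps.append((0.0, 0.0))
    levels = irreversible_levels(traj)
    if assumption is Assumption.MIDPOINT:
        from .midpoint import expected_midpoints

        exp = {m.level: m.time for m in expected_midpoints(traj)}
        for level, t_att in levels:
            steps.append((exp.get(level, t_att), level))
    else:
        for level, _ in levels:
            ev = event_time(traj, level, assumption)
            steps.append((ev.time, level))
    steps.sort(key=lambda s: (s[1], s[0]))
    return IrreversiblePath(traj.patient_id, assumption, steps)
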