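"""Expected midpoint survival-time measures (Exp records).

The true crossing time of an irreversible endpoint is interval-censored:
it lies between the last record strictly below the level and the visit
that attains it.  The midpoint assumption places each event at the
expectation of that interval.  When several grid levels are first attained
at the same visit (the record skipped levels, e.g. 1.5 -> 3.0), the
censoring interval is shared: it is partitioned into equal subintervals,
one per skipped level, and each level is placed at the midpoint of its
subinterval,

    t_j = t_a + (2j - 1) (t_b - t_a) / (2k),   j = 1..k,

which for k = 1 reduces to the adjacent-midpoint rule (t_a + t_b) / 2.
Transitory (Ot) observations can never shrink a bracket: the left edge is
the last record *strictly below* the run's lowest level, and the attaining
run interval contains no other visits by construction.
"""
from __future__ import annotations

import logging
from itertools import groupby

from .paths import irreversible_levels
from .records import (
    ExpectedMeasure,
    PatientTrajectory,
    Source,
    VisitRecord,
)

log = logging.getLogger(__name__)


def expected_midpoints(traj: PatientTrajectory) -> list[ExpectedMeasure]:
    """One expected midpoint measure per irreversible level >= 1.0.

    Returns an empty list when no level >= 1.0 is irreversible.  If the
    first censoring bracket has no lower edge (onset unknown and no record
    below the first irreversible level), no Exp measure is generated for
    that run and a warning is logged; those levels enter estimation models
    at their maximum survival time.
    """
    levels = irreversible_levels(traj)
    out: list[ExpectedMeasure] = []
    # maximal runs of consecutive grid levels sharing one attainment visit
    for t_b, group in groupby(levels, key=lambda le: le[1]):
        run = [lv for lv, _ in group]
        t_a = _last_strictly_below(traj, run[0], t_b)
        if t_a is None:
            log.warning(
                "patient %s: no record below EDSS %.1f before t=%.3f; "
                "levels %s enter models at maximum survival time",
                traj.patient_id,
                run[0],
                t_b,
                run,
            )
            continue
        k = len(run)
        width = t_b - t_a
        for j, level in enumerate(run, start=1):
            out.append(
                ExpectedMeasure(
                    patient_id=traj.patient_id,
                    level=level,
                    time=t_a + (2 * j - 1) * width / (2 * k),
                    bracket=(t_a, t_b),
                )
            )
    return out


def _last_strictly_below(traj, level, before):
    best = None
    for v in traj.visits:
        if v.source is Source.EXPECTED_MIDPOINT:
            continue
        if v.time >= before:
            break
        if v.edss < level:
            best = v.time
    return best


def augment(traj: PatientTrajectory) -> PatientTrajectory:
    """Trajectory with one Exp record per irreversible level added.

    Clinical records and the onset anchor are never modified or removed.
    Pre-existing Exp records are recomputed, making the operation
    idempotent.
    """
    base = [v for v in traj.visits if v.source is not Source.EXPECTED_MIDPOINT]
    exp_records = [
        VisitRecord(
            patient_id=traj.patient_id,
            time=m.time,
            edss=m.level,
            source=Source.EXPECTED_MIDPOINT,
        )
        for m in expected_midpoints(traj)
    ]
    return traj.with_visits(base + exp_records)


def augment_cohort(trajectories) -> list[PatientTrajectory]:
    """Vectorised convenience wrapper: :func:`augment` over a cohort."""
    return [augment(t) if t.clinical_visits else t for t in trajectories]
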