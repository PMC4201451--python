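"""Censoring-bias size metrics: assessment rates and censoring windows.

Missing-observation bias is summarised two ways:

* **assessment rates** -- EDSS records per patient-year, measured either
  from first to last clinical observation or from onset to last clinical
  observation, counting clinical observations only (``obs``) or clinical
  plus expected midpoint measures (``obs_plus_exp``);
* **censoring windows** -- the partition of a patient's timeline into the
  left-censored window (onset to first clinical observation), the
  interval-censored window (first to last), and the right-censored window
  (last observation to an analysis horizon, reported only when a horizon
  is supplied).

The primary rate is pooled (total records / total person-years); the mean
of per-patient rates is emitted alongside because "per-patient-per-year"
admits both readings.  Patients with a single clinical visit have a
zero-length first-to-last window and are excluded from first-to-last
rates (logged) but included onset-to-last.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import PatientTrajectory, Source

log = logging.getLogger(__name__)

BASES = ("first_to_last", "onset_to_last")
COUNTINGS = ("obs", "obs_plus_exp")


@dataclass(frozen=True)
class AssessmentRateSummary:
    group: str
    basis: str
    counting: str
    n_patients: int
    total_records: int
    person_years: float
    rate: float
    rate_mean_of_ratios: float
    mean_onset_to_first: float
    n_excluded_single_visit: int


@dataclass(frozen=True)
class CensoringPartition:
    """Contiguous left / interval / right censoring windows for one patient."""

    patient_id: str
    left_window: Optional[tuple[float, float]]
    interval_window: tuple[float, float]
    right_window: Optional[tuple[float, float]]
    left_defined: bool


def _patient_arrays(traj: PatientTrajectory):
    clin = [v.time for v in traj.visits if v.source is Source.CLINICAL]
    exp = [v.time for v in traj.visits if v.source is Source.EXPECTED_MIDPOINT]
    return np.asarray(clin), np.asarray(exp)


def assessment_rate(
    trajectories: Iterable[PatientTrajectory],
    basis: str = "first_to_last",
    counting: str = "obs",
    group: str = "all",
) -> AssessmentRateSummary:
    """Pooled EDSS assessment rate per patient-year for one group.

    Onset anchor records are never counted as observations.  For patients
    with Exp measures under ``obs_plus_exp`` counting, the onset-to-first
    gap uses the first Exp time (the earliest moment the record places any
    disability), otherwise the first clinical observation time.
    """
    if basis not in BASES:
        raise ValueError(f"basis must be one of {BASES}")
    if counting not in COUNTINGS:
        raise ValueError(f"counting must be one of {COUNTINGS}")
    n_records = 0
    person_years = 0.0
    per_patient_rates = []
    onset_to_first = []
    n_patients = 0
    n_excluded = 0
    for traj in trajectories:
        clin, exp = _patient_arrays(traj)
        if len(clin) == 0:
            continue
        count = len(clin) + (len(exp) if counting == "obs_plus_exp" else 0)
        if basis == "first_to_last":
            window = clin[-1] - clin[0]
            if window <= 0:
                n_excluded += 1
                continue
        else:
            window = clin[-1]
            if window <= 0:
                n_excluded += 1
                continue
        n_patients += 1
        n_records += count
        person_years += float(window)
        per_patient_rates.append(count / window)
        if counting == "obs_plus_exp" and len(exp):
            onset_to_first.append(min(exp[0], clin[0]))
        else:
            onset_to_first.append(clin[0])
    if n_patients == 0:
        raise ValueError(f"group {group!r}: no patients with a usable window")
    if n_excluded:
        log.info(
            "group %s (%s): excluded %d patients with a zero-length window",
            group,
            basis,
            n_excluded,
        )
    return AssessmentRateSummary(
        group=group,
        basis=basis,
        counting=counting,
        n_patients=n_patients,
        total_records=n_records,
        person_years=person_years,
        rate=n_records / person_years,
        rate_mean_of_ratios=float(np.mean(per_patient_rates)),
        mean_onset_to_first=float(np.mean(onset_to_first)),
        n_excluded_single_visit=n_excluded,
    )


def censoring_partition(
    traj: PatientTrajectory, horizon: Optional[float] = None
) -> CensoringPartition:
    """Left / interval / right censoring windows for one patient.

    The right window is reported only when an analysis horizon is supplied
    (undefined is not zero); the left window is undefined when onset is
    unknown.
    """
    clin, _ = _patient_arrays(traj)
    if len(clin) == 0:
        raise ValueError(f"patient {traj.patient_id}: no clinical visits")
    first, last = float(clin[0]), float(clin[-1])
    left = (0.0, first) if traj.onset_known else None
    right = None
    if horizon is not None:
        if horizon < last:
            raise ValueError(
                f"patient {traj.patient_id}: horizon {horizon} precedes the "
                f"last clinical observation at {last}"
            )
        right = (last, float(horizon))
    return CensoringPartition(
        patient_id=traj.patient_id,
        left_window=left,
        interval_window=(first, last),
        right_window=right,
        left_defined=traj.onset_known,
    )


def era_report(
    trajectories: Sequence[PatientTrajectory],
    era_bounds: Sequence[tuple[float, float]],
    basis: str = "first_to_last",
    counting: str = "obs",
) -> pd.DataFrame:
    """Assessment rates by calendar era.

    ``era_bounds`` is a sequence of inclusive calendar-year windows
    ``(lo, hi)`` (windows may overlap, as study periods do when a policy
    change splits a year).  A patient contributes to every era in which
    they have at least one clinical observation; records are restricted to
    the era window via calendar year = onset year + years-since-onset.
    Eras with no observations are omitted with a warning.
    """
    rows = []
    for lo, hi in era_bounds:
        label = f"{int(lo)}-{int(hi)}"
        restricted = []
        for traj in trajectories:
            if traj.onset_year is None:
                continue
            visits = [
                v
                for v in traj.visits
                if v.source is not Source.ONSET_ANCHOR
                and lo <= traj.onset_year + v.time <= hi
            ]
            if any(v.source is Source.CLINICAL for v in visits):
                restricted.append(
                    PatientTrajectory(
                        patient_id=traj.patient_id,
                        visits=visits,
                        onset_known=traj.onset_known,
                        group_labels=traj.group_labels,
                        onset_year=traj.onset_year,
                    )
                )
        if not restricted:
            log.warning("era %s: no observations; omitted", label)
            continue
        try:
            summary = assessment_rate(
                restricted, basis=basis, counting=counting, group=label
            )
        except ValueError:
            log.warning("era %s: no usable windows; omitted", label)
            continue
        rows.append(
            {
                "era": label,
                "n_patients": summary.n_patients,
                "total_records": summary.total_records,
                "person_years": summary.person_years,
                "rate": summary.rate,
                "rate_mean_of_ratios": summary.rate_mean_of_ratios,
                "mean_onset_to_first": summary.mean_onset_to_first,
            }
        )
    return pd.DataFrame(rows)
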