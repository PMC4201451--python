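"""Kaplan-Meier survival at irreversible EDSS endpoints 1-9.

The probability of surviving an irreversible endpoint is p = 1 - f, with f
the cumulative probability of failure (irreversible progression).  Event
times come from path construction under the chosen survival-time
assumption; patients who never irreversibly reach a level are
right-censored at their last clinical observation under *every*
assumption (midpoint adjustment never moves censoring times).  Estimation
is delegated to lifelines' product-limit estimator; events precede
censorings at tied times (the standard convention).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter

from . import grid
from .midpoint import expected_midpoints
from .paths import event_time, irreversible_levels, _validate_endpoint_level
from .records import (
    Assumption,
    EndpointEvent,
    EventStatus,
    PatientTrajectory,
)

log = logging.getLogger(__name__)

#: Endpoint levels displayed by default: integer EDSS 1..9.
DEFAULT_LEVELS = tuple(float(k) for k in range(1, 10))


@dataclass(frozen=True)
class OnsetCohortFilter:
    """Synthetic-onset-cohort eligibility: assessed onset and a minimum
    number of natural-history clinical observations."""

    min_clinical_obs: int = 2
    require_onset: bool = True

    def __post_init__(self) -> None:
        if self.min_clinical_obs < 1:
            raise ValueError("min_clinical_obs must be >= 1")


def select_onset_cohort(
    trajectories: Iterable[PatientTrajectory],
    cohort_filter: OnsetCohortFilter = OnsetCohortFilter(),
) -> list[PatientTrajectory]:
    """Patients eligible for the synthetic onset cohort."""
    trajectories = list(trajectories)
    kept = [
        t
        for t in trajectories
        if t.n_clinical >= cohort_filter.min_clinical_obs
        and (t.onset_known or not cohort_filter.require_onset)
    ]
    log.info(
        "onset cohort: kept %d of %d patients (min_clinical_obs=%d, require_onset=%s)",
        len(kept),
        len(trajectories),
        cohort_filter.min_clinical_obs,
        cohort_filter.require_onset,
    )
    return kept


def endpoint_events(
    trajectories: Iterable[PatientTrajectory],
    level: float,
    assumption: Assumption | str,
) -> list[EndpointEvent]:
    """Per-patient event/censor times at one endpoint level.

    Under the midpoint assumption event times are the expected midpoint
    measures (falling back to the maximum time for levels whose bracket has
    no lower edge); censoring times are the last clinical observation under
    every assumption.
    """
    level = _validate_endpoint_level(level)
    assumption = Assumption.parse(assumption)
    events: list[EndpointEvent] = []
    skipped = 0
    for traj in trajectories:
        if not traj.clinical_visits:
            skipped += 1
            continue
        if assumption is Assumption.MIDPOINT:
            irr = dict(irreversible_levels(traj))
            if level not in irr:
                ev = EndpointEvent(
                    traj.patient_id,
                    level,
                    assumption,
                    traj.last_clinical_time,
                    EventStatus.RIGHT_CENSORED,
                )
            else:
                exp = {m.level: m.time for m in expected_midpoints(traj)}
                ev = EndpointEvent(
                    traj.patient_id,
                    level,
                    assumption,
                    exp.get(level, irr[level]),
                    EventStatus.EVENT,
                )
        else:
            ev = event_time(traj, level, assumption)
        events.append(ev)
    if skipped:
        log.info("endpoint level %.1f: skipped %d patients with no clinical visits", level, skipped)
    return events


@dataclass
class KMCurve:
    """Product-limit survival function for one endpoint level."""

    level: float
    assumption: Assumption
    times: np.ndarray
    survival: np.ndarray
    n_events: int
    n_censored: int
    ci_lower: Optional[np.ndarray] = None
    ci_upper: Optional[np.ndarray] = None

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation S(t) (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if len(self.times) == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)

    @property
    def median(self) -> Optional[float]:
        """Smallest event time with S <= 0.5; None if never crossed."""
        below = np.nonzero(self.survival <= 0.5)[0]
        if len(below) == 0:
            return None
        return float(self.times[below[0]])


def km_fit(events: Sequence[EndpointEvent], with_ci: bool = False) -> KMCurve:
    """Fit the product-limit estimator to one level's endpoint events.

    ``with_ci`` attaches Greenwood-type 95% bands (off by default; point
    curves are the primary display).
    """
    if not events:
        raise ValueError("no endpoint events to fit")
    levels = {ev.level for ev in events}
    assumptions = {ev.assumption for ev in events}
    if len(levels) != 1 or len(assumptions) != 1:
        raise ValueError(
            "all events in one Kaplan-Meier fit must share level and "
            f"assumption (got levels {levels}, assumptions {assumptions})"
        )
    durations = np.array([ev.time for ev in events])
    observed = np.array([ev.observed for ev in events], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    times = np.unique(durations[observed])
    survival = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    ci_lo = ci_hi = None
    if with_ci and len(times):
        ci = kmf.confidence_interval_survival_function_
        idx = ci.index.searchsorted(times, side="right") - 1
        ci_lo = ci.iloc[idx, 0].to_numpy(dtype=float)
        ci_hi = ci.iloc[idx, 1].to_numpy(dtype=float)
    return KMCurve(
        level=levels.pop(),
        assumption=assumptions.pop(),
        times=times,
        survival=survival,
        n_events=int(observed.sum()),
        n_censored=int((~observed).sum()),
        ci_lower=ci_lo,
        ci_upper=ci_hi,
    )


def km_suite(
    trajectories: Sequence[PatientTrajectory],
    assumption: Assumption | str,
    levels: Sequence[float] = DEFAULT_LEVELS,
    cohort_filter: Optional[OnsetCohortFilter] = None,
) -> list[KMCurve]:
    """One survival curve per endpoint level (default integer EDSS 1-9)."""
    if cohort_filter is not None:
        trajectories = select_onset_cohort(trajectories, cohort_filter)
    return [
        km_fit(endpoint_events(trajectories, level, assumption))
        for level in levels
    ]


def median_survival(curve: KMCurve) -> Optional[float]:
    """Median survival time of a fitted curve (None when undefined)."""
    return curve.median
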