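"""Synthetic relapsing-onset MS natural-history cohort generator.

Emulates the statistical structure the downstream analysis assumes so the
whole pipeline is testable without clinical data:

* latent disability is linear in years since onset, ``D(t) = min(beta t, 10)``,
  observed floored to the last attained EDSS grid level (an endpoint counts
  as reached only once latent disability attains it);
* the first clinic visit occurs an exponential onset delay after symptom
  onset (clinical records typically begin years after onset), and later
  visits follow a gamma renewal process, giving irregular positive gaps
  with controllable mean and variance;
* relapses arrive as a Poisson process; a visit falling inside a relapse
  window reads the floored latent value plus a transitory elevation,
  producing Ot-type observations that later readings contradict;
* follow-up ends at a gamma-distributed horizon (right-censoring at the
  last visit).

Defaults mirror a 1979-2010 natural-history clinic population: progression
0.17 EDSS/year, ~0.45 assessments per patient-year onset-to-last, mean
onset-to-first-visit gap 2.5 years, mean follow-up 20 years.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from . import grid
from .records import PatientTrajectory, Source, VisitRecord

__all__ = [
    "SimulationParams",
    "simulate_trajectory",
    "simulate_cohort",
    "simulate_era_mixture",
]


@dataclass
class SimulationParams:
    """Parameters of the natural-history cohort generator.

    All rates are per year, all durations in years.  ``beta_true`` is the
    latent progression rate in EDSS/year and is the recoverable estimand of
    the rate model; ``beta_sd > 0`` draws per-patient rates from a gamma
    distribution with that mean and standard deviation.
    """

    n_patients: int = 250
    beta_true: float = 0.17
    beta_sd: float = 0.0
    visit_gap_mean: float = 2.0
    visit_gap_shape: float = 2.0
    onset_delay_mean: float = 2.5
    followup_mean: float = 20.0
    followup_shape: float = 10.0
    relapse_rate: float = 0.5
    relapse_height: float = 1.0
    relapse_duration_mean: float = 0.15
    onset_year_range: tuple[int, int] = (1979, 2005)
    era_label: Optional[str] = None
    seed: int = 20100

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        nonneg = [
            "beta_true",
            "beta_sd",
            "visit_gap_mean",
            "onset_delay_mean",
            "followup_mean",
            "relapse_rate",
            "relapse_height",
            "relapse_duration_mean",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("visit_gap_shape", "followup_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.visit_gap_mean <= 0:
            raise ValueError("visit_gap_mean must be > 0")

    def replace(self, **kw) -> "SimulationParams":
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        if "onset_year_range" in d:
            d["onset_year_range"] = tuple(d["onset_year_range"])
        return cls(**d)


def simulate_trajectory(
    params: SimulationParams,
    rng: np.random.Generator,
    patient_id: str = "P0",
) -> PatientTrajectory:
    """One patient drawn from the natural-history model.

    The trajectory always carries the onset anchor (t=0, EDSS 0); a patient
    whose follow-up ends before the onset delay has no clinical visits.
    """
    beta = params.beta_true
    if params.beta_sd > 0 and beta > 0:
        shape = (beta / params.beta_sd) ** 2
        beta = rng.gamma(shape, beta / shape)
    delay = (
        rng.exponential(params.onset_delay_mean)
        if params.onset_delay_mean > 0
        else 0.0
    )
    followup = rng.gamma(
        params.followup_shape, params.followup_mean / params.followup_shape
    )

    times: list[float] = []
    t = delay
    gap_scale = params.visit_gap_mean / params.visit_gap_shape
    while t <= followup:
        times.append(t)
        t += rng.gamma(params.visit_gap_shape, gap_scale)

    n_rel = rng.poisson(params.relapse_rate * followup)
    rel_start = rng.uniform(0.0, followup, size=n_rel)
    rel_end = rel_start + rng.exponential(
        params.relapse_duration_mean, size=n_rel
    )

    visits = [VisitRecord(patient_id, 0.0, 0.0, Source.ONSET_ANCHOR)]
    for tv in times:
        if tv <= 0.0:
            continue  # a zero onset delay would collide with the anchor
        base = grid.grid_floor(min(beta * tv, 10.0))
        in_relapse = bool(np.any((rel_start <= tv) & (tv < rel_end)))
        if in_relapse and params.relapse_height > 0:
            value = grid.snap_up(min(base + params.relapse_height, 10.0))
        else:
            value = base
        visits.append(VisitRecord(patient_id, tv, value))

    onset_year = float(
        rng.integers(params.onset_year_range[0], params.onset_year_range[1] + 1)
    )
    labels = {params.era_label} if params.era_label else set()
    return PatientTrajectory(
        patient_id=patient_id,
        visits=visits,
        onset_known=True,
        group_labels=frozenset(labels),
        onset_year=onset_year,
    )


def simulate_cohort(
    params: SimulationParams, seed: Optional[int] = None
) -> list[PatientTrajectory]:
    """``n_patients`` independent trajectories from one seeded stream."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    width = len(str(params.n_patients))
    prefix = f"{params.era_label}-" if params.era_label else "P"
    return [
        simulate_trajectory(params, rng, f"{prefix}{i + 1:0{width}d}")
        for i in range(params.n_patients)
    ]


def simulate_era_mixture(
    era_params: Sequence[SimulationParams], seed: Optional[int] = None
) -> list[PatientTrajectory]:
    """Concatenated cohorts emulating assessment regimes that changed over
    time (e.g. a sparse 1979-1988 era versus a dense 1998-2010 era).

    Each block keeps its own parameters; patient ids are prefixed with the
    era label so subgroup estimates can be compared downstream.
    """
    if seed is None:
        seeds = [p.seed for p in era_params]
    else:
        seeds = [int(s.generate_state(1)[0] % (2**31))
                 for s in np.random.SeedSequence(seed).spawn(len(era_params))]
    cohort: list[PatientTrajectory] = []
    for i, (p, s) in enumerate(zip(era_params, seeds)):
        if p.era_label is None:
            p = p.replace(era_label=f"era{i + 1}")
        cohort.extend(simulate_cohort(p, seed=s))
    return cohort
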