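"""Core domain types: visit records, patient trajectories, endpoint events.

Time is measured in real years since assessed symptom onset (yso).  A
trajectory is the time-ordered visit history of one patient, optionally
prefixed by a synthetic onset anchor (EDSS 0 at t = 0), which encodes the
convention that relapsing-onset MS disability starts at zero at symptom
onset.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from . import grid


class Source(str, Enum):
    """Provenance of a visit record."""

    CLINICAL = "clinical"
    ONSET_ANCHOR = "onset_anchor"
    EXPECTED_MIDPOINT = "expected_midpoint"


class ObservationLabel(str, Enum):
    """Role of an observation relative to the irreversible progression path.

    ``Of``/``Om``/``Or`` are the first / intermediate / last repeat clinical
    observations on an irreversible EDSS plateau; ``Ot`` is a transitorily
    high observation later contradicted by a strictly lower reading (e.g. a
    relapse); ``Oo`` is the synthetic onset observation and ``Exp`` an
    expected midpoint measure.
    """

    ONSET = "Oo"
    FIRST = "Of"
    INTERMEDIATE = "Om"
    LAST_REPEAT = "Or"
    TRANSITORY = "Ot"
    EXPECTED = "Exp"


class Assumption(str, Enum):
    """Survival-time assumption at interval-censored progression events."""

    MAXIMUM = "maximum"
    MINIMUM = "minimum"
    MIDPOINT = "midpoint"

    @classmethod
    def parse(cls, value: "Assumption | str") -> "Assumption":
        if isinstance(value, cls):
            return value
        aliases = {"max": "maximum", "min": "minimum", "mid": "midpoint"}
        v = str(value).lower()
        return cls(aliases.get(v, v))


class EventStatus(str, Enum):
    EVENT = "event"
    RIGHT_CENSORED = "right_censored"


@dataclass(frozen=True)
class VisitRecord:
    """One timed EDSS measurement for one patient."""

    patient_id: str
    time: float
    edss: float
    source: Source = Source.CLINICAL

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(
                f"patient {self.patient_id}: negative time {self.time!r}"
            )
        object.__setattr__(self, "edss", grid.validate(self.edss))
        object.__setattr__(self, "time", float(self.time))
        if self.source is Source.ONSET_ANCHOR and (
            self.time != 0.0 or self.edss != 0.0
        ):
            raise ValueError(
                f"patient {self.patient_id}: onset anchor must be "
                f"(t=0, EDSS=0), got (t={self.time}, EDSS={self.edss})"
            )


@dataclass
class PatientTrajectory:
    """Time-ordered visit sequence for one patient plus onset metadata."""

    patient_id: str
    visits: list[VisitRecord]
    onset_known: bool = False
    group_labels: frozenset[str] = field(default_factory=frozenset)
    onset_year: Optional[float] = None

    def __post_init__(self) -> None:
        self.group_labels = frozenset(self.group_labels)
        times = [v.time for v in self.visits]
        for a, b, v in zip(times, times[1:], self.visits[1:]):
            if b <= a:
                raise ValueError(
                    f"patient {self.patient_id}: visit times must be strictly "
                    f"increasing (t={b} follows t={a}); same-day repeats are "
                    "an input error"
                )
        anchors = [v for v in self.visits if v.source is Source.ONSET_ANCHOR]
        if len(anchors) > 1:
            raise ValueError(
                f"patient {self.patient_id}: more than one onset anchor"
            )
        if anchors and self.visits[0].source is not Source.ONSET_ANCHOR:
            raise ValueError(
                f"patient {self.patient_id}: onset anchor must be the first "
                "record"
            )

    # -- convenience views ------------------------------------------------

    @property
    def anchor(self) -> Optional[VisitRecord]:
        if self.visits and self.visits[0].source is Source.ONSET_ANCHOR:
            return self.visits[0]
        return None

    @property
    def clinical_visits(self) -> list[VisitRecord]:
        return [v for v in self.visits if v.source is Source.CLINICAL]

    @property
    def expected_visits(self) -> list[VisitRecord]:
        return [v for v in self.visits if v.source is Source.EXPECTED_MIDPOINT]

    @property
    def n_clinical(self) -> int:
        return len(self.clinical_visits)

    @property
    def last_clinical_time(self) -> float:
        clin = self.clinical_visits
        if not clin:
            raise ValueError(
                f"patient {self.patient_id}: no clinical visits"
            )
        return clin[-1].time

    def with_visits(self, visits: Iterable[VisitRecord]) -> "PatientTrajectory":
        return PatientTrajectory(
            patient_id=self.patient_id,
            visits=sorted(visits, key=lambda v: (v.time, v.source is not Source.ONSET_ANCHOR)),
            onset_known=self.onset_known,
            group_labels=self.group_labels,
            onset_year=self.onset_year,
        )


@dataclass(frozen=True)
class EndpointEvent:
    """Event or censoring time at one irreversible EDSS endpoint level."""

    patient_id: str
    level: float
    assumption: Assumption
    time: float
    status: EventStatus

    @property
    def observed(self) -> bool:
        return self.status is EventStatus.EVENT


@dataclass(frozen=True)
class ExpectedMeasure:
    """Expected midpoint survival-time measure for one endpoint level."""

    patient_id: str
    level: float
    time: float
    bracket: tuple[float, float]


@dataclass
class IrreversiblePath:
    """Monotone (time, level) progression path under one assumption."""

    patient_id: str
    assumption: Assumption
    steps: list[tuple[float, float]]
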