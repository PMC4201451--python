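"""Irreversible-endpoint detection, labelling, and path construction."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_traj
from oracles import brute_irreversible_levels

from edss_midpath import grid
from edss_midpath.paths import (
    build_path,
    event_time,
    irreversible_levels,
    label_observations,
)
from edss_midpath.records import (
    EventStatus,
    ObservationLabel as L,
    PatientTrajectory,
    VisitRecord,
)

GRID_VALUES = [float(v) for v in grid.GRID]

visit_values = st.lists(st.sampled_from(GRID_VALUES), min_size=1, max_size=25)


def _traj_from_values(values, anchor=False):
    return make_traj("h", [(float(i + 1), v) for i, v in enumerate(values)],
                     anchor=anchor)


# -- irreversible level detection ----------------------------------------


@pytest.mark.parametrize(
    "visits,expected",
    [
        # a plateau then a one-step rise: the skipped 1.5 and the 2.0 are
        # both first held from the rise visit
        ([(2, 1.0), (4, 1.0), (6, 2.0)],
         [(1.0, 2.0), (1.5, 6.0), (2.0, 6.0)]),
        # transitory 2.0 at t=1 is contradicted at t=2; only 1.0 survives
        ([(1, 2.0), (2, 1.0), (3, 1.0)], [(1.0, 1.0)]),
        # nothing at or above 1.0 reached
        ([(5, 0.0)], []),
    ],
)
def test_irreversible_levels_worked_examples(visits, expected):
    traj = make_traj("p", [(float(t), float(e)) for t, e in visits])
    assert irreversible_levels(traj) == expected
    times = [float(t) for t, _ in visits]
    edss = [float(e) for _, e in visits]
    assert brute_irreversible_levels(times, edss) == expected


def test_empty_trajectory_is_an_error():
    traj = PatientTrajectory("p", [])
    with pytest.raises(ValueError, match="no clinical visits"):
        irreversible_levels(traj)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(values=visit_values)
def test_production_matches_brute_force_oracle(values):
    traj = _traj_from_values(values)
    times = [v.time for v in traj.clinical_visits]
    assert irreversible_levels(traj) == brute_irreversible_levels(times, values)


# -- observation labelling -----------------------------------------------


@pytest.mark.parametrize(
    "visits,anchor,expected",
    [
        ([(1, 2.0), (2, 1.0), (3, 1.0)], False,
         [L.TRANSITORY, L.FIRST, L.LAST_REPEAT]),
        ([(2, 1.0), (4, 1.0)], True, [L.ONSET, L.FIRST, L.LAST_REPEAT]),
        ([(1, 1.0), (2, 2.0), (3, 3.0)], False, [L.FIRST, L.FIRST, L.FIRST]),
    ],
)
def test_labels_worked_examples(visits, anchor, expected):
    traj = make_traj("p", [(float(t), float(e)) for t, e in visits], anchor=anchor)
    assert [lab for _, lab in label_observations(traj)] == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(values=visit_values)
def test_labels_are_exhaustive_and_transitory_is_exact(values):
    traj = _traj_from_values(values)
    labelled = label_observations(traj)
    assert len(labelled) == len(traj.visits)
    for k, (rec, lab) in enumerate(labelled):
        later_lower = any(v < values[k] for v in values[k + 1:])
        assert (lab is L.TRANSITORY) == later_lower


@settings(max_examples=150, deadline=None, derandomize=True)
@given(values=visit_values, new_value=st.sampled_from(GRID_VALUES))
def test_relabelling_stability_under_appended_visits(values, new_value):
    traj = _traj_from_values(values)
    before = [lab for _, lab in label_observations(traj)]
    extended = _traj_from_values(list(values) + [new_value])
    after = [lab for _, lab in label_observations(extended)][: len(values)]
    if new_value >= max(values):
        # appending at/above the running maximum cannot create reversions:
        # Ot flags are untouched and Of/Om roles are preserved
        for b, a in zip(before, after):
            assert (b is L.TRANSITORY) == (a is L.TRANSITORY)
            if b in (L.FIRST, L.INTERMEDIATE):
                assert a is b
    for b, a, v in zip(before, after, values):
        if b is L.TRANSITORY:
            assert a is L.TRANSITORY  # never Ot -> non-Ot
        if v > new_value:
            assert a is L.TRANSITORY  # contradicted by the new reading


# -- event times under maximum / minimum ---------------------------------


def test_event_time_boundary_assumptions_on_anchored_step():
    traj = make_traj("p", [(2.0, 1.0)], anchor=True)
    ev_max = event_time(traj, 1.0, "max")
    ev_min = event_time(traj, 1.0, "min")
    assert (ev_max.time, ev_max.status) == (2.0, EventStatus.EVENT)
    assert (ev_min.time, ev_min.status) == (0.0, EventStatus.EVENT)


def test_event_time_reversion_censors_at_last_visit(reversion_trajectory):
    ev = event_time(reversion_trajectory, 2.0, "max")
    assert ev.status is EventStatus.RIGHT_CENSORED
    assert ev.time == 3.0


def test_event_time_rejects_off_grid_and_sub_one_levels(toy_trajectory):
    with pytest.raises(ValueError):
        event_time(toy_trajectory, 0.5, "max")
    with pytest.raises(ValueError):
        event_time(toy_trajectory, 1.2, "max")
    with pytest.raises(ValueError):
        event_time(toy_trajectory, 10.0, "max")


# -- path construction ---------------------------------------------------


def test_build_path_worked_examples(toy_trajectory):
    assert build_path(toy_trajectory, "max").steps == [
        (0.0, 0.0), (2.0, 1.0), (6.0, 1.5), (6.0, 2.0)]
    assert build_path(toy_trajectory, "min").steps == [
        (0.0, 0.0), (0.0, 1.0), (4.0, 1.5), (4.0, 2.0)]
    flat = make_traj("p", [(1.0, 0.0), (2.0, 0.0)], anchor=True)
    assert build_path(flat, "max").steps == [(0.0, 0.0)]


@settings(max_examples=150, deadline=None, derandomize=True)
@given(values=visit_values, anchored=st.booleans())
def test_paths_monotone_and_bracketed(values, anchored):
    traj = _traj_from_values(values, anchor=anchored)
    first_time = traj.clinical_visits[0].time
    for assumption in ("max", "min"):
        steps = build_path(traj, assumption).steps
        assert all(a[0] <= b[0] and a[1] < b[1]
                   for a, b in zip(steps, steps[1:]))
    for level, t_att in irreversible_levels(traj):
        t_min = event_time(traj, level, "min").time
        t_max = event_time(traj, level, "max").time
        assert t_min <= t_max
        if t_min == t_max and not anchored:
            # degenerate bracket only when the attaining visit opens the record
            assert t_att == first_time
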