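import numpy as np
import pytest

from edss_midpath.records import PatientTrajectory, Source, VisitRecord


def make_traj(pid, visits, anchor=False, onset_year=None, groups=()):
    """Build a trajectory from (time, edss) pairs, optionally anchored."""
    recs = []
    if anchor:
        recs.append(VisitRecord(pid, 0.0, 0.0, Source.ONSET_ANCHOR))
    recs.extend(VisitRecord(pid, t, e) for t, e in visits)
    return PatientTrajectory(
        pid,
        recs,
        onset_known=anchor,
        group_labels=frozenset(groups),
        onset_year=onset_year,
    )


@pytest.fixture
def toy_trajectory():
    """Anchored worked example: plateau at 1.0 then a two-level jump."""
    return make_traj("toy", [(2.0, 1.0), (4.0, 1.0), (6.0, 2.0)], anchor=True)


@pytest.fixture
def reversion_trajectory():
    """Transitory high at t=1 contradicted by later lower readings."""
    return make_traj("rev", [(1.0, 2.0), (2.0, 1.0), (3.0, 1.0)])


@pytest.fixture(scope="session")
def fuzzed_visit_series():
    """Deterministic pool of random trajectories on the EDSS grid."""
    from edss_midpath import grid

    rng = np.random.default_rng(987)
    pool = []
    for _ in range(400):
        n = int(rng.integers(1, 30))
        times = np.sort(rng.uniform(0.0, 30.0, n)) + np.arange(n) * 1e-6
        edss = grid.GRID[rng.integers(0, len(grid.GRID), n)]
        pool.append(list(zip(times.tolist(), edss.tolist())))
    return pool
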