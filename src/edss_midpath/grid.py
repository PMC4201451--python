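"""The EDSS measurement grid.

The Expanded Disability Status Scale is an ordinal neurological disability
score: 0 (normal examination), then half-point steps from 1.0 up to 10.0
(death due to MS).  0.5 is not a scale value.  The scale behaves
near-linearly (equal-interval) only in the range 0-6.5, which is what
licenses arithmetic rate-of-change modelling there; rate models in this
package default to records with EDSS <= 6.
"""
from __future__ import annotations

import numpy as np

#: Admissible EDSS values: {0.0} U {1.0, 1.5, ..., 10.0}.
GRID = np.concatenate(([0.0], np.arange(2, 21) * 0.5))

#: Upper bound of the range used by rate-of-change models.
RATE_RANGE_MAX = 6.0

#: Upper bound of the near-linear (equal-interval) range of the scale.
LINEAR_RANGE_MAX = 6.5


def is_on_grid(value: float) -> bool:
    """True if ``value`` is an admissible EDSS score."""
    v = float(value)
    if v == 0.0:
        return True
    return 1.0 <= v <= 10.0 and (2.0 * v) == round(2.0 * v)


def validate(value: float) -> float:
    """Return ``value`` as a float, raising ``ValueError`` if off-grid."""
    if not is_on_grid(value):
        raise ValueError(
            f"EDSS value {value!r} is not on the admissible grid "
            "({0} and half-point steps from 1 to 10; 0.5 does not exist)"
        )
    return float(value)


def grid_floor(x: float) -> float:
    """Largest admissible EDSS value <= ``x`` (the last attained level).

    Values in [0, 1) floor to 0: there is no grid point between 0 and 1.
    """
    if x < 0:
        raise ValueError(f"cannot floor negative disability {x!r}")
    idx = int(np.searchsorted(GRID, min(x, 10.0), side="right")) - 1
    return float(GRID[idx])


def snap_up(x: float) -> float:
    """Smallest admissible EDSS value >= ``x`` (capped at 10)."""
    if x <= 0:
        return 0.0
    if x >= 10.0:
        return 10.0
    idx = int(np.searchsorted(GRID, x, side="left"))
    return float(GRID[idx])


def levels_up_to(hi: float) -> np.ndarray:
    """Grid levels from 1.0 up to and including ``hi`` (empty if hi < 1)."""
    if hi < 1.0:
        return np.empty(0)
    return GRID[(GRID >= 1.0) & (GRID <= hi)].copy()
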