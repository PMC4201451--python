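"""Independent brute-force oracles used by the test suite.

These deliberately transcribe the defining statements literally (quadratic
scans, explicit product-limit arithmetic, plain Monte-Carlo) and stay
independent of the package's implementations.
"""
from __future__ import annotations

import numpy as np

GRID = [0.0] + [1.0 + 0.5 * k for k in range(19)]


def brute_irreversible_levels(times, edss):
    """Quadratic scan of the irreversibility definition.

    Level e is irreversible iff some visit has EDSS >= e and no later visit
    has EDSS < e; attainment is the earliest such visit.
    """
    out = []
    n = len(edss)
    for e in GRID:
        if e < 1.0 or e == 10.0:  # death is not an analysis endpoint
            continue
        for i in range(n):
            if edss[i] >= e and all(edss[j] >= e for j in range(i + 1, n)):
                out.append((float(e), float(times[i])))
                break
    return out


def product_limit(times, observed):
    """Hand-computed Kaplan-Meier estimate.

    Returns (event_times, survival) stepping at distinct observed-event
    times; events precede censorings at tied times.
    """
    times = np.asarray(times, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    at_risk = len(times)
    s = 1.0
    out_t, out_s = [], []
    for t in np.unique(times):
        here = times == t
        d = int((here & observed).sum())
        c = int((here & ~observed).sum())
        if d > 0:
            s *= 1.0 - d / at_risk
            out_t.append(float(t))
            out_s.append(s)
        at_risk -= d + c
    return np.array(out_t), np.array(out_s)


def mc_visit_counts(gap_mean, gap_shape, onset_delay_mean, followup_mean,
                    followup_shape, n, seed):
    """Monte-Carlo expectation of clinical visits per patient under the
    renewal visit process (first visit at the onset delay, then gamma
    gaps, until a gamma follow-up horizon)."""
    rng = np.random.default_rng(seed)
    counts = np.empty(n)
    for i in range(n):
        delay = rng.exponential(onset_delay_mean)
        followup = rng.gamma(followup_shape, followup_mean / followup_shape)
        t = delay
        k = 0
        while t <= followup:
            k += 1
            t += rng.gamma(gap_shape, gap_mean / gap_shape)
        counts[i] = k
    return counts
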