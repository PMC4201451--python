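"""Fixed-effects rate-of-change model and assumption comparisons."""
import numpy as np
import pandas as pd
import pytest

from edss_midpath.rate import (
    RateEstimate,
    assumption_records,
    compare_assumptions,
    fit_rate,
    variability_report,
)
from edss_midpath.records import Assumption, ObservationLabel
from edss_midpath.simulate import SimulationParams, simulate_cohort


def linear_records(beta=0.2, n_patients=4):
    rows = []
    for p in range(n_patients):
        for t in (5.0, 10.0, 15.0, 20.0, 25.0):
            rows.append({"patient_id": f"p{p}", "time": t, "edss": beta * t})
    return pd.DataFrame(rows)


def test_exact_recovery_on_noiseless_linear_data():
    est = fit_rate(linear_records(), n_boot=20, seed=1)
    assert abs(est.beta_yso - 0.2) < 1e-10
    # closed-form through-origin slope is the independent oracle
    df = linear_records()
    oracle = (df.time * df.edss).sum() / (df.time**2).sum()
    assert est.beta_yso == pytest.approx(oracle, abs=1e-12)
    assert est.ci95[0] <= est.beta_yso <= est.ci95[1]
    assert est.n_patients == 4 and est.n_records == 20


def test_all_zero_records_give_zero_slope():
    df = linear_records(beta=0.0)
    assert fit_rate(df, n_boot=10, seed=1).beta_yso == 0.0


def test_range_filter_applies_to_record_values():
    df = linear_records(beta=0.4)  # values 2..10; records above 6 dropped
    est = fit_rate(df, range_max=6.0, n_boot=10, seed=1)
    assert est.n_records == 12  # 3 of 5 visits per patient are <= 6
    assert abs(est.beta_yso - 0.4) < 1e-10


def test_no_records_in_range_is_an_error():
    df = linear_records(beta=1.0).query("edss > 6")
    with pytest.raises(ValueError, match="no records"):
        fit_rate(df, range_max=6.0, n_boot=10, seed=1)


def test_fe_variant_matches_pooled_on_origin_anchored_data_and_errors():
    df = linear_records()
    est = fit_rate(df, variant="fe", n_boot=10, seed=1)
    assert abs(est.beta_yso - 0.2) < 1e-10
    single = pd.concat(
        [df, pd.DataFrame([{"patient_id": "solo", "time": 3.0, "edss": 1.0}])]
    )
    with pytest.raises(ValueError, match="2 records"):
        fit_rate(single, variant="fe", n_boot=10, seed=1)


def test_bootstrap_is_deterministic_and_b_independent_point_estimate():
    df = linear_records().assign(
        edss=lambda d: np.clip(d.edss + (d.time % 3) * 0.1, 0, 10)
    )
    a = fit_rate(df, n_boot=200, seed=42)
    b = fit_rate(df, n_boot=200, seed=42)
    c = fit_rate(df, n_boot=10, seed=42)
    assert a.ci95 == b.ci95 and a.se == b.se
    assert a.beta_yso == c.beta_yso


def test_assumption_records_populating_contract():
    cohort = simulate_cohort(SimulationParams(n_patients=30, seed=2))
    rec_max = assumption_records(cohort, "maximum")
    rec_mid = assumption_records(cohort, "midpoint")
    rec_min = assumption_records(cohort, "minimum")
    n_clin = sum(t.n_clinical for t in cohort)
    n_anchor = sum(t.anchor is not None for t in cohort)
    assert len(rec_max) == n_clin + n_anchor
    from edss_midpath.paths import irreversible_levels

    n_irr = sum(
        len(irreversible_levels(t)) for t in cohort if t.clinical_visits
    )
    # midpoint adds one Exp row per bracketed irreversible level; with
    # anchors present every level is bracketed
    assert len(rec_mid) == n_clin + n_anchor + n_irr
    assert len(rec_min) == n_clin + n_anchor + n_irr
    assert set(rec_mid.source) >= {"clinical", "onset_anchor", "expected_midpoint"}


def test_transitory_exclusion_flag_drops_ot_records():
    cohort = simulate_cohort(SimulationParams(n_patients=60, relapse_rate=1.5, seed=8))
    with_ot = assumption_records(cohort, "maximum", include_transitory=True)
    without = assumption_records(cohort, "maximum", include_transitory=False)
    assert len(without) < len(with_ot)


def test_boundary_assumptions_bracket_the_midpoint_slope():
    """On noiseless linear cohorts the minimum / midpoint / maximum record
    sets order the fitted slopes fastest to slowest."""
    for s in range(10):
        cohort = simulate_cohort(
            SimulationParams(n_patients=100, relapse_rate=0.0, seed=100 + s)
        )
        betas = {
            a: fit_rate(assumption_records(cohort, a), n_boot=2, seed=1).beta_yso
            for a in ("minimum", "midpoint", "maximum")
        }
        assert betas["minimum"] >= betas["midpoint"] >= betas["maximum"]


def test_compare_assumptions_identical_records_and_mismatch_error():
    df = linear_records()
    est = fit_rate(df, n_boot=50, seed=7)
    cmp_ = compare_assumptions(est, est, df, df, n_boot=50, seed=7)
    assert cmp_.pct_faster == 0.0
    assert cmp_.diff_ci95[0] <= 0.0 <= cmp_.diff_ci95[1]
    assert not cmp_.significant
    with pytest.raises(ValueError, match="same patient set"):
        compare_assumptions(est, est, df, df[df.patient_id != "p0"],
                            n_boot=10, seed=7)


def test_midpoint_recovers_true_rate_better_than_maximum():
    p = SimulationParams(n_patients=200, seed=55)
    cohort = simulate_cohort(p)
    rm = assumption_records(cohort, "midpoint")
    rx = assumption_records(cohort, "maximum")
    em = fit_rate(rm, assumption="midpoint", n_boot=199, seed=5)
    ex = fit_rate(rx, assumption="maximum", n_boot=199, seed=5)
    assert ex.beta_yso < em.beta_yso
    assert abs(em.beta_yso - p.beta_true) < abs(ex.beta_yso - p.beta_true)
    cmp_ = compare_assumptions(em, ex, rm, rx, n_boot=199, seed=5)
    assert cmp_.significant and cmp_.diff > 0
    assert cmp_.pct_faster == pytest.approx(
        100 * (em.beta_yso - ex.beta_yso) / ex.beta_yso
    )


def test_variability_report_closed_forms_and_errors():
    def est(beta, group, assumption):
        return RateEstimate(beta, 0.01, (beta - 0.02, beta + 0.02),
                            Assumption.parse(assumption), group, 10, 50)

    rep = variability_report(
        [est(0.15, "a", "max"), est(0.15, "b", "max"),
         est(0.10, "a", "mid"), est(0.20, "b", "mid")]
    )
    assert rep.loc["maximum", "cv"] == 0.0
    sd = np.std([0.10, 0.20], ddof=1)
    assert rep.loc["midpoint", "cv"] == pytest.approx(sd / 0.15)
    assert rep.loc["midpoint", "range"] == pytest.approx(0.10)
    with pytest.raises(ValueError, match="2"):
        variability_report([est(0.15, "a", "max")])
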