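"""Fixed-effects rate-of-change model for progression speed (EDSS/year).

Progression speed in the near-linear range is the slope ``beta_yso`` of
EDSS on years-since-onset.  Because EDSS = 0 at onset is assumed, the
default variant ("pooled") is a through-origin pooled OLS over all records
with EDSS <= 6; an optional "fe" variant adds per-patient intercepts via
the within (demeaning) transformation.  Point fits go through statsmodels;
uncertainty comes from a patient-level cluster bootstrap, resampling
patients with replacement and recombining per-patient sufficient
statistics (which reproduces the OLS estimate exactly on each resample).

The survival-time assumption enters through how the record set is
populated: *maximum* uses clinical observations only; *midpoint* adds the
expected midpoint measures; *minimum* adds minimum-survival-time measures.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import grid
from .midpoint import expected_midpoints
from .paths import event_time, irreversible_levels
from .records import Assumption, PatientTrajectory, Source

__all__ = [
    "RateEstimate",
    "AssumptionComparison",
    "assumption_records",
    "fit_rate",
    "compare_assumptions",
    "variability_report",
]

DEFAULT_SEED = 20100
DEFAULT_BOOT = 999


@dataclass(frozen=True)
class RateEstimate:
    """Slope of EDSS on years-since-onset with bootstrap uncertainty."""

    beta_yso: float
    se: float
    ci95: tuple[float, float]
    assumption: Optional[Assumption]
    group: str
    n_patients: int
    n_records: int
    variant: str = "pooled"


@dataclass(frozen=True)
class AssumptionComparison:
    """Midpoint-vs-maximum speed-up with paired-bootstrap uncertainty."""

    group: str
    beta_mid: float
    beta_max: float
    pct_faster: float
    diff: float
    diff_ci95: tuple[float, float]
    significant: bool
    n_boot: int
    seed: int


def assumption_records(
    trajectories: Iterable[PatientTrajectory],
    assumption: Assumption | str,
    include_transitory: bool = True,
) -> pd.DataFrame:
    """Long-format record table populating the rate model.

    Maximum: onset anchors + clinical observations.  Midpoint: those plus
    expected midpoint measures.  Minimum: those plus minimum-survival-time
    measures (one per irreversible level).  ``include_transitory=False``
    drops Ot-labelled clinical observations.
    """
    assumption = Assumption.parse(assumption)
    rows: list[tuple[str, float, float, str]] = []
    for traj in trajectories:
        keep_clin = traj.clinical_visits
        if not include_transitory and keep_clin:
            from .paths import label_observations
            from .records import ObservationLabel

            lab = dict(
                (id(v), l) for v, l in label_observations(traj)
            )
            keep_clin = [
                v
                for v in keep_clin
                if lab[id(v)] is not ObservationLabel.TRANSITORY
            ]
        if traj.anchor is not None:
            rows.append((traj.patient_id, 0.0, 0.0, "onset_anchor"))
        for v in keep_clin:
            rows.append((traj.patient_id, v.time, v.edss, "clinical"))
        if not traj.clinical_visits:
            continue
        if assumption is Assumption.MIDPOINT:
            for m in expected_midpoints(traj):
                rows.append(
                    (traj.patient_id, m.time, m.level, "expected_midpoint")
                )
        elif assumption is Assumption.MINIMUM:
            for level, _ in irreversible_levels(traj):
                ev = event_time(traj, level, Assumption.MINIMUM)
                rows.append((traj.patient_id, ev.time, level, "minimum_time"))
    return pd.DataFrame(
        rows, columns=["patient_id", "time", "edss", "source"]
    )


def _group_sums(records: pd.DataFrame, variant: str):
    """Per-patient sufficient statistics for the slope estimator."""
    if variant == "pooled":
        x = records["time"].to_numpy(float)
        y = records["edss"].to_numpy(float)
    else:  # within transformation
        g = records.groupby("patient_id")
        if (g["time"].count() < 2).any():
            bad = g["time"].count()
            bad = bad[bad < 2].index.tolist()
            raise ValueError(
                "per-patient-intercept variant needs >= 2 records per "
                f"patient; offending patients: {bad[:5]}"
            )
        x = (records["time"] - g["time"].transform("mean")).to_numpy(float)
        y = (records["edss"] - g["edss"].transform("mean")).to_numpy(float)
    pid = records["patient_id"].to_numpy()
    df = pd.DataFrame({"pid": pid, "sxy": x * y, "sxx": x * x})
    sums = df.groupby("pid", sort=True).sum()
    return sums["sxy"].to_numpy(), sums["sxx"].to_numpy(), sums.index.to_numpy()


def _bootstrap_betas(sxy, sxx, n_boot, rng):
    n = len(sxy)
    idx = rng.integers(0, n, size=(n_boot, n))
    num = sxy[idx].sum(axis=1)
    den = sxx[idx].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        betas = num / den
    return betas[np.isfinite(betas)]


def fit_rate(
    records: pd.DataFrame,
    range_max: float = grid.RATE_RANGE_MAX,
    variant: str = "pooled",
    n_boot: int = DEFAULT_BOOT,
    seed: int = DEFAULT_SEED,
    assumption: Assumption | str | None = None,
    group: str = "all",
) -> RateEstimate:
    """Fit the progression-rate model on a populated record table.

    ``records`` needs columns ``patient_id``, ``time``, ``edss``; only
    records with EDSS <= ``range_max`` enter the fit (the filter applies to
    the record's value, not the patient's eventual maximum).
    """
    if variant not in ("pooled", "fe"):
        raise ValueError(f"unknown variant {variant!r}")
    fit_df = records[records["edss"] <= range_max]
    if fit_df.empty:
        raise ValueError(f"no records with EDSS <= {range_max}")
    if variant == "pooled":
        x = fit_df["time"].to_numpy(float)
        y = fit_df["edss"].to_numpy(float)
        if not np.any(x != 0):
            raise ValueError("all record times are zero; slope is undefined")
        beta = float(sm.OLS(y, x[:, None]).fit().params[0])
    else:
        sxy_c, sxx_c, _ = _group_sums(fit_df, "fe")
        g = fit_df.groupby("patient_id")
        xd = (fit_df["time"] - g["time"].transform("mean")).to_numpy(float)
        yd = (fit_df["edss"] - g["edss"].transform("mean")).to_numpy(float)
        if not np.any(xd != 0):
            raise ValueError("no within-patient time variation; slope undefined")
        beta = float(sm.OLS(yd, xd[:, None]).fit().params[0])
    sxy, sxx, pids = _group_sums(fit_df, variant)
    rng = np.random.default_rng(seed)
    betas = _bootstrap_betas(sxy, sxx, n_boot, rng)
    se = float(np.std(betas, ddof=1)) if len(betas) > 1 else float("nan")
    lo, hi = np.percentile(betas, [2.5, 97.5]) if len(betas) else (np.nan,) * 2
    lo, hi = min(float(lo), beta), max(float(hi), beta)
    return RateEstimate(
        beta_yso=beta,
        se=se,
        ci95=(lo, hi),
        assumption=Assumption.parse(assumption) if assumption else None,
        group=group,
        n_patients=len(pids),
        n_records=int(len(fit_df)),
        variant=variant,
    )


def compare_assumptions(
    est_mid: RateEstimate,
    est_max: RateEstimate,
    records_mid: pd.DataFrame,
    records_max: pd.DataFrame,
    range_max: float = grid.RATE_RANGE_MAX,
    variant: str = "pooled",
    n_boot: int = DEFAULT_BOOT,
    seed: int = DEFAULT_SEED,
) -> AssumptionComparison:
    """Paired patient-level bootstrap of beta(midpoint) - beta(maximum).

    Patients are resampled with replacement once per draw and both slopes
    are recomputed on the same resample, so the difference CI reflects the
    paired design.  The speed-up is flagged significant iff the 95%
    percentile CI of the difference excludes 0.
    """
    mid = records_mid[records_mid["edss"] <= range_max]
    mx = records_max[records_max["edss"] <= range_max]
    pats_mid = set(mid["patient_id"])
    pats_max = set(mx["patient_id"])
    if pats_mid != pats_max:
        raise ValueError(
            "assumption comparison requires the same patient set under both "
            f"assumptions ({len(pats_mid)} vs {len(pats_max)} patients)"
        )
    sxy_m, sxx_m, pid_m = _group_sums(mid, variant)
    sxy_x, sxx_x, pid_x = _group_sums(mx, variant)
    assert list(pid_m) == list(pid_x)
    n = len(pid_m)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        bm = sxy_m[idx].sum(1) / sxx_m[idx].sum(1)
        bx = sxy_x[idx].sum(1) / sxx_x[idx].sum(1)
    diff = bm - bx
    diff = diff[np.isfinite(diff)]
    lo, hi = (np.percentile(diff, [2.5, 97.5]) if len(diff) else (np.nan,) * 2)
    d = est_mid.beta_yso - est_max.beta_yso
    return AssumptionComparison(
        group=est_mid.group,
        beta_mid=est_mid.beta_yso,
        beta_max=est_max.beta_yso,
        pct_faster=100.0 * d / est_max.beta_yso,
        diff=d,
        diff_ci95=(float(lo), float(hi)),
        significant=bool(lo > 0 or hi < 0),
        n_boot=n_boot,
        seed=seed,
    )


def variability_report(estimates: Iterable[RateEstimate]) -> pd.DataFrame:
    """Dispersion of subgroup slopes per assumption.

    Returns one row per assumption with the coefficient of variation
    (sample SD / mean) and the range of ``beta_yso`` across subgroups;
    requires >= 2 subgroups per assumption.
    """
    rows = {}
    by_assumption: dict[str, list[float]] = {}
    for est in estimates:
        key = est.assumption.value if est.assumption else "unspecified"
        by_assumption.setdefault(key, []).append(est.beta_yso)
    for key, betas in by_assumption.items():
        if len(betas) < 2:
            raise ValueError(
                f"assumption {key!r} has {len(betas)} subgroup estimate(s); "
                ">= 2 are needed for a dispersion summary"
            )
        arr = np.asarray(betas)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1))
        rows[key] = {
            "n_groups": len(arr),
            "mean": mean,
            "sd": sd,
            "cv": sd / mean if mean != 0 else float("inf"),
            "min": float(arr.min()),
            "max": float(arr.max()),
            "range": float(arr.max() - arr.min()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
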