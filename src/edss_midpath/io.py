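"""Delimited-text readers and writers for visit tables and cohort metadata.

Input is a long-format table with one row per clinic visit: columns
``patient_id``, ``time`` (years since onset) or ``date`` (ISO date), and
``edss``; an optional metadata table supplies ``onset_year`` (calendar
year of assessed symptom onset) and semicolon-separated ``groups``.  A
year-only onset is resolved to mid-year (July 2) when converting dates,
with a 365.25-day year.  Output adds ``source`` and ``label`` columns and
round-trips clinical records bit-exactly.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from . import grid
from .records import PatientTrajectory, Source, VisitRecord

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

DAYS_PER_YEAR = 365.25


def _infer_sep(path: PathLike, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_metadata(path: PathLike, sep: Optional[str] = None) -> pd.DataFrame:
    """Cohort metadata: ``patient_id``, optional ``onset_year``, ``groups``."""
    meta = pd.read_csv(path, sep=_infer_sep(path, sep), dtype={"patient_id": str})
    if "patient_id" not in meta.columns:
        raise ValueError(f"metadata {path}: missing column 'patient_id'")
    return meta.set_index("patient_id")


def read_visits(
    path: PathLike,
    sep: Optional[str] = None,
    metadata: Union[PathLike, pd.DataFrame, None] = None,
    insert_onset_anchor: bool = True,
    include_expected: bool = False,
) -> list[PatientTrajectory]:
    """Read a visit table into validated, time-sorted trajectories.

    Rows flagged ``source=expected_midpoint`` are regenerated quantities,
    not measurements; they are skipped unless ``include_expected`` is set
    (used when re-loading this package's own augmented output).  When onset
    metadata is available (or an anchor row is present) and
    ``insert_onset_anchor`` is enabled, the trajectory starts with the
    synthetic onset record (t=0, EDSS 0).
    """
    df = pd.read_csv(
        path,
        sep=_infer_sep(path, sep),
        dtype={"patient_id": str},
        float_precision="round_trip",
    )
    required = {"patient_id", "edss"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "time" not in df.columns and "date" not in df.columns:
        raise ValueError(f"{path}: need a 'time' or 'date' column")

    meta = None
    if metadata is not None:
        meta = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata, sep)

    if "time" not in df.columns:
        if meta is None or "onset_year" not in meta.columns:
            raise ValueError(
                f"{path}: a 'date' column needs onset_year metadata to be "
                "converted to years since onset"
            )
        dates = pd.to_datetime(df["date"])
        onset_years = df["patient_id"].map(meta["onset_year"])
        if onset_years.isna().any():
            bad = df.loc[onset_years.isna(), "patient_id"].iloc[0]
            raise ValueError(f"{path}: no onset_year for patient {bad!r}")
        origins = pd.to_datetime(
            pd.DataFrame(
                {"year": onset_years.astype(int), "month": 7, "day": 2}
            )
        )
        df = df.assign(time=(dates - origins).dt.days / DAYS_PER_YEAR)

    if "source" not in df.columns:
        df = df.assign(source=Source.CLINICAL.value)
    df["source"] = df["source"].fillna(Source.CLINICAL.value)

    for pos, row in enumerate(df.itertuples(index=False), start=2):
        if not grid.is_on_grid(row.edss):
            raise ValueError(
                f"{path} row {pos}: EDSS value {row.edss!r} is not on the "
                "admissible grid"
            )
        if row.time < 0:
            raise ValueError(f"{path} row {pos}: negative time {row.time!r}")
    dup = df.duplicated(subset=["patient_id", "time"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (patient, time) = "
            f"({row['patient_id']!r}, {row['time']!r})"
        )

    if not include_expected:
        n_exp = int((df["source"] == Source.EXPECTED_MIDPOINT.value).sum())
        if n_exp:
            log.info("%s: skipped %d expected_midpoint rows", path, n_exp)
        df = df[df["source"] != Source.EXPECTED_MIDPOINT.value]

    trajectories = []
    for pid, sub in df.groupby("patient_id", sort=True):
        sub = sub.sort_values("time", kind="mergesort")
        onset_known = bool(
            (sub["source"] == Source.ONSET_ANCHOR.value).any()
        )
        groups: frozenset[str] = frozenset()
        onset_year = None
        if meta is not None and pid in meta.index:
            m = meta.loc[pid]
            if "onset_year" in meta.columns and pd.notna(m.get("onset_year")):
                onset_year = float(m["onset_year"])
                onset_known = True
            if "groups" in meta.columns and pd.notna(m.get("groups")):
                groups = frozenset(str(m["groups"]).split(";"))
        visits = [
            VisitRecord(
                patient_id=str(pid),
                time=float(r.time),
                edss=float(r.edss),
                source=Source(r.source),
            )
            for r in sub.itertuples(index=False)
        ]
        has_anchor = any(v.source is Source.ONSET_ANCHOR for v in visits)
        has_time_zero = any(v.time == 0.0 for v in visits)
        if insert_onset_anchor and onset_known and not has_anchor and not has_time_zero:
            visits = [
                VisitRecord(str(pid), 0.0, 0.0, Source.ONSET_ANCHOR)
            ] + visits
        elif not insert_onset_anchor:
            visits = [v for v in visits if v.source is not Source.ONSET_ANCHOR]
        trajectories.append(
            PatientTrajectory(
                patient_id=str(pid),
                visits=visits,
                onset_known=onset_known,
                group_labels=groups,
                onset_year=onset_year,
            )
        )
    log.info("%s: read %d records for %d patients", path, len(df), len(trajectories))
    return trajectories


def write_augmented(
    trajectories: Iterable[PatientTrajectory],
    path: PathLike,
    sep: Optional[str] = None,
    include_labels: bool = True,
) -> None:
    """Write trajectories (possibly holding Exp records) to delimited text.

    Columns: ``patient_id``, ``time``, ``edss``, ``source`` and, when
    ``include_labels`` is set, the observation ``label`` (Oo/Of/Om/Or/Ot/
    Exp).  An empty cohort produces a header-only file.
    """
    from .paths import label_observations

    rows = []
    for traj in trajectories:
        if include_labels and traj.clinical_visits:
            labelled = label_observations(traj)
        else:
            labelled = [(v, None) for v in traj.visits]
        for v, lab in labelled:
            rows.append(
                {
                    "patient_id": v.patient_id,
                    "time": v.time,
                    "edss": v.edss,
                    "source": v.source.value,
                    "label": lab.value if lab is not None else "",
                }
            )
    cols = ["patient_id", "time", "edss", "source", "label"]
    out = pd.DataFrame(rows, columns=cols)
    # full-precision floats so that read(write(x)) is bit-exact
    for col in ("time", "edss"):
        out[col] = out[col].map(repr)
    out.to_csv(path, sep=_infer_sep(path, sep), index=False)
    log.info("%s: wrote %d records", path, len(out))
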