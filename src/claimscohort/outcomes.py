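"""Claims-based severe-infection phenotyping.

Four outcome definitions are supported.  The *original* (validated)
algorithm declares a severe infection when a confirmed (non-suspected)
infection diagnosis is the primary reason for a hospitalization and an
immunological infection test is recorded between the month before the
admission date and the discharge date; onset is the admission date.  The
sensitivity definitions relax it:

* ``def1`` replaces the immunological test with an intravenous
  antibacterial course starting during the hospitalization;
* ``def2`` drops the hospitalization anchor entirely — a confirmed
  infection diagnosis linked in time to an IV antibacterial course, with
  onset at the course start;
* ``def3`` is the original definition after removing COVID-coded
  diagnoses.

Antibacterial *courses* are maximal runs of daily IV antibacterial
records, merging gaps of at most ``gap_days`` missing days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .claims import ClaimsDatabase, CodeLists, IntegrityError, match_codes

__all__ = [
    "OutcomeDefinition",
    "ORIGINAL",
    "DEF1",
    "DEF2",
    "DEF3",
    "DEFINITIONS",
    "build_antibacterial_courses",
    "detect_severe_infections",
    "first_events",
    "summarize_antibacterial_courses",
]

EVENT_COLUMNS = [
    "patient_id", "onset_date", "definition", "hospitalization_id",
    "diagnosis_row", "lab_row", "course_id",
]


@dataclass(frozen=True)
class OutcomeDefinition:
    name: str
    requires_hospitalization: bool
    requires_primary_reason: bool
    requires_immunological_test: bool
    requires_iv_antibacterial: bool
    exclude_covid_codes: bool


ORIGINAL = OutcomeDefinition("original", True, True, True, False, False)
DEF1 = OutcomeDefinition("def1", True, True, False, True, False)
DEF2 = OutcomeDefinition("def2", False, False, False, True, False)
DEF3 = OutcomeDefinition("def3", True, True, True, False, True)
DEFINITIONS = {d.name: d for d in (ORIGINAL, DEF1, DEF2, DEF3)}


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=EVENT_COLUMNS)


def build_antibacterial_courses(
    db: ClaimsDatabase,
    codes: CodeLists,
    gap_days: int = 1,
    patient_scope: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Merge daily IV antibacterial records into treatment courses.

    Two records belong to the same course when at most ``gap_days`` days
    are missing between them (dates ``d1 < d2`` merge iff
    ``d2 - d1 <= gap_days + 1``).  Duration is the calendar span
    ``end - start + 1``.  ``setting_at_start`` is inpatient if any record
    on the start date is inpatient.
    """
    d = db.drugs
    mask = match_codes(d["drug_code"], codes.iv_antibacterial) & (
        d["route"] == "intravenous")
    if patient_scope is not None:
        mask &= d["patient_id"].isin(set(patient_scope))
    abx = d[mask].sort_values(["patient_id", "administration_date"], kind="stable")
    if not len(abx):
        return pd.DataFrame(columns=[
            "course_id", "patient_id", "start_date", "end_date", "duration_days",
            "setting_at_start", "drug_codes"])

    gap = abx.groupby("patient_id")["administration_date"].diff().dt.days
    new_course = gap.isna() | (gap > gap_days + 1)
    abx = abx.assign(course_id=new_course.cumsum().astype(int) - 1)

    agg = abx.groupby("course_id").agg(
        patient_id=("patient_id", "first"),
        start_date=("administration_date", "min"),
        end_date=("administration_date", "max"),
        drug_codes=("drug_code", lambda s: ",".join(sorted(set(s)))),
    )
    agg["duration_days"] = (agg["end_date"] - agg["start_date"]).dt.days + 1
    start_rows = abx[abx["administration_date"].eq(
        abx["course_id"].map(agg["start_date"]))]
    inpatient_start = start_rows.groupby("course_id")["setting"].agg(
        lambda s: "inpatient" if (s == "inpatient").any() else "outpatient")
    agg["setting_at_start"] = inpatient_start
    return agg.reset_index()[[
        "course_id", "patient_id", "start_date", "end_date", "duration_days",
        "setting_at_start", "drug_codes"]]


def _confirmed_infection_dx(
    db: ClaimsDatabase, codes: CodeLists, exclude_covid: bool,
    patient_scope: Iterable[str] | None,
) -> pd.DataFrame:
    dx = db.diagnoses
    mask = match_codes(dx["code"], codes.infection) & ~dx["suspected"]
    if exclude_covid:
        mask &= ~match_codes(dx["code"], codes.covid19)
    if patient_scope is not None:
        mask &= dx["patient_id"].isin(set(patient_scope))
    out = dx[mask].copy()
    out["diagnosis_row"] = out.index
    return out


def detect_severe_infections(
    db: ClaimsDatabase,
    codes: CodeLists,
    definition: OutcomeDefinition,
    patient_scope: Iterable[str] | None = None,
    interval: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    first_only: bool = False,
    gap_days: int = 1,
    def2_lookback_days: int = 7,
    courses: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Detect severe-infection events under one outcome definition.

    Hospitalization-anchored definitions yield one event per qualifying
    hospitalization (onset = admission date); ``def2`` yields one event per
    qualifying (confirmed infection diagnosis, IV antibacterial course)
    pair (onset = course start date).  Suspected diagnoses never qualify.
    ``interval`` restricts onsets to a closed global date interval;
    ``first_only`` keeps the earliest event per patient.  Precomputed
    ``courses`` (from :func:`build_antibacterial_courses`) may be passed to
    avoid recomputation.
    """
    needs_courses = definition.requires_iv_antibacterial
    if needs_courses and courses is None:
        courses = build_antibacterial_courses(db, codes, gap_days, patient_scope)

    dx = _confirmed_infection_dx(db, codes, definition.exclude_covid_codes, patient_scope)

    if definition.requires_hospitalization:
        ev = _detect_hospital_anchored(db, dx, definition, courses, def2_lookback_days)
    else:
        ev = _detect_diagnosis_course_pairs(dx, courses, def2_lookback_days)
    ev["definition"] = definition.name

    if interval is not None:
        lo, hi = interval
        ev = ev[(ev["onset_date"] >= lo) & (ev["onset_date"] <= hi)]
    ev = ev.sort_values(["patient_id", "onset_date"], kind="stable").reset_index(drop=True)
    if first_only and len(ev):
        ev = ev.drop_duplicates("patient_id", keep="first")
    return ev[EVENT_COLUMNS].reset_index(drop=True) if len(ev) else _empty_events()


def _detect_hospital_anchored(
    db: ClaimsDatabase, dx: pd.DataFrame, definition: OutcomeDefinition,
    courses: pd.DataFrame | None, def2_lookback_days: int = 7,
) -> pd.DataFrame:
    prim = dx[dx["primary_for_hospitalization"] & dx["linked_hospitalization_id"].notna()]
    if not len(prim):
        return _empty_events()
    hosp = db.hospitalizations.set_index("hospitalization_id")
    ev = prim.merge(
        hosp, left_on="linked_hospitalization_id", right_index=True,
        suffixes=("", "_h"))
    ev = ev[ev["patient_id"] == ev["patient_id_h"]]
    # one event per hospitalization: keep the first qualifying diagnosis
    ev = (ev.sort_values(["linked_hospitalization_id", "diagnosis_row"], kind="stable")
            .drop_duplicates("linked_hospitalization_id", keep="first"))
    ev = ev.rename(columns={"linked_hospitalization_id": "hospitalization_id"})

    ev["lab_row"] = pd.NA
    if definition.requires_immunological_test:
        labs = db.labs[db.labs["category"] == "immunological_infection"].copy()
        labs["lab_row"] = labs.index
        m = ev.merge(labs[["patient_id", "test_date", "lab_row"]],
                     on="patient_id", suffixes=("", "_l"))
        window_lo = (pd.PeriodIndex(m["admission_date"], freq="M") - 1).start_time
        ok = m[(m["test_date"] >= window_lo) & (m["test_date"] <= m["discharge_date"])]
        matched = ok.groupby("hospitalization_id")["lab_row_l"
                            if "lab_row_l" in ok.columns else "lab_row"].first()
        ev["lab_row"] = ev["hospitalization_id"].map(matched)
        ev = ev[ev["lab_row"].notna()]

    ev["course_id"] = pd.NA
    if definition.requires_iv_antibacterial:
        if courses is None or not len(courses):
            return _empty_events()
        m = ev.merge(courses[["patient_id", "course_id", "start_date", "end_date"]],
                     on="patient_id", suffixes=("", "_c"))
        cid = "course_id_c" if "course_id_c" in m.columns else "course_id"
        # course starts during the hospitalization AND satisfies the same
        # diagnosis-month linkage as the diagnosis+course definition, so
        # hospitalization-anchored course events nest inside it exactly
        month_start = pd.PeriodIndex(m["diagnosis_month"], freq="M").start_time
        month_end = pd.PeriodIndex(m["diagnosis_month"], freq="M").end_time.normalize()
        ok = m[(m["start_date"] >= m["admission_date"])
               & (m["start_date"] <= m["discharge_date"])
               & (month_start <= m["end_date_c" if "end_date_c" in m.columns
                                   else "end_date"])
               & (month_end >= m["start_date"]
                  - pd.Timedelta(days=def2_lookback_days))]
        matched = ok.sort_values("start_date").groupby("hospitalization_id")[cid].first()
        ev["course_id"] = ev["hospitalization_id"].map(matched)
        ev = ev[ev["course_id"].notna()]

    ev = ev.rename(columns={"admission_date": "onset_date"})
    ev["definition"] = definition.name
    return ev[["patient_id", "onset_date", "definition", "hospitalization_id",
               "diagnosis_row", "lab_row", "course_id"]]


def _detect_diagnosis_course_pairs(
    dx: pd.DataFrame, courses: pd.DataFrame | None, lookback_days: int,
) -> pd.DataFrame:
    """Diagnosis-month × course linkage: the confirmed infection diagnosis
    month must overlap ``[course start − lookback_days, course end]``."""
    if courses is None or not len(courses) or not len(dx):
        return _empty_events()
    m = dx[["patient_id", "diagnosis_month", "diagnosis_row"]].merge(
        courses[["patient_id", "course_id", "start_date", "end_date"]], on="patient_id")
    if not len(m):
        return _empty_events()
    month_start = pd.PeriodIndex(m["diagnosis_month"], freq="M").start_time
    month_end = pd.PeriodIndex(m["diagnosis_month"], freq="M").end_time.normalize()
    ok = m[(month_start <= m["end_date"])
           & (month_end >= m["start_date"] - pd.Timedelta(days=lookback_days))]
    ev = ok.rename(columns={"start_date": "onset_date"}).copy()
    ev["hospitalization_id"] = pd.NA
    ev["lab_row"] = pd.NA
    ev["definition"] = ""
    return ev[["patient_id", "onset_date", "definition", "hospitalization_id",
               "diagnosis_row", "lab_row", "course_id"]]


def first_events(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    horizon_days: int = 210,
) -> pd.DataFrame:
    """Earliest event per patient with onset in [index, index + horizon]."""
    if not len(events):
        return _empty_events()
    idx = cohort.set_index("patient_id")["index_date"]
    ev = events.join(idx, on="patient_id")
    ev = ev[ev["index_date"].notna()
            & (ev["onset_date"] >= ev["index_date"])
            & (ev["onset_date"] <= ev["index_date"] + pd.Timedelta(days=horizon_days))]
    ev = ev.sort_values(["patient_id", "onset_date"], kind="stable")
    return ev.drop_duplicates("patient_id", keep="first")[EVENT_COLUMNS].reset_index(drop=True)


def summarize_antibacterial_courses(
    events: pd.DataFrame,
    courses: pd.DataFrame,
    groups: pd.Series,
) -> pd.DataFrame:
    """Course-length and treatment-setting summary for ``def2`` events.

    One row per treatment group: n, mean/SD/median/min/max of course
    duration (days), and inpatient/outpatient counts at course start.
    ``groups`` maps patient_id -> group label.
    """
    if not len(events):
        return pd.DataFrame(columns=[
            "group", "n", "mean", "sd", "median", "min", "max",
            "n_inpatient", "n_outpatient", "pct_inpatient"])
    ev = events.merge(
        courses[["course_id", "duration_days", "setting_at_start"]],
        on="course_id", how="left")
    if ev["duration_days"].isna().any():
        missing = ev.loc[ev["duration_days"].isna(), "patient_id"].tolist()[:5]
        raise IntegrityError(f"events without resolvable course: {missing}")
    ev["group"] = ev["patient_id"].map(groups)
    rows = []
    for group, sub in ev.groupby("group"):
        dur = sub["duration_days"].astype(float)
        n_in = int((sub["setting_at_start"] == "inpatient").sum())
        rows.append({
            "group": group, "n": len(sub),
            "mean": dur.mean(), "sd": dur.std(ddof=1) if len(dur) > 1 else np.nan,
            "median": dur.median(), "min": dur.min(), "max": dur.max(),
            "n_inpatient": n_in, "n_outpatient": len(sub) - n_in,
            "pct_inpatient": 100.0 * n_in / len(sub),
        })
    return pd.DataFrame(rows)
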