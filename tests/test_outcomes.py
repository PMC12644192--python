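"""Outcome-definition truth table, course merging, and nesting properties."""

import pandas as pd
import pytest

from claimscohort.outcomes import (
    DEF1,
    DEF2,
    DEF3,
    DEFINITIONS,
    ORIGINAL,
    build_antibacterial_courses,
    detect_severe_infections,
    summarize_antibacterial_courses,
)
from claimscohort.simulate import SimulationParameters, generate_claims_database

from _helpers import bc_dx, drug, make_db, patient


def _episode_db(
    *,
    suspected=False,
    primary=True,
    has_hosp=True,
    test_date="2021-01-15",
    course_start=None,
    dx_code="A41.0",
):
    """One hospitalization episode 2021-02-10..2021-02-20 with optional parts."""
    diagnoses = [{
        "patient_id": "P1", "code": dx_code, "diagnosis_month": "2021-02",
        "suspected": suspected,
        "primary_for_hospitalization": primary and has_hosp,
        "linked_hospitalization_id": "H1" if (primary and has_hosp) else None,
    }]
    hosp = ([{"hospitalization_id": "H1", "patient_id": "P1",
              "admission_date": "2021-02-10", "discharge_date": "2021-02-20"}]
            if has_hosp else [])
    labs = ([{"patient_id": "P1", "test_date": test_date}] if test_date else [])
    drugs = []
    if course_start:
        start = pd.Timestamp(course_start)
        for k in range(5):
            drugs.append(drug("P1", "ABX01", (start + pd.Timedelta(days=k)).strftime(
                "%Y-%m-%d"), 500, setting="inpatient"))
    return make_db(
        patients=[patient("P1")], diagnoses=diagnoses, hospitalizations=hosp,
        labs=labs, drugs=drugs)


def test_all_four_criteria_met_original_event(codes):
    db = _episode_db()
    ev = detect_severe_infections(db, codes, ORIGINAL)
    assert len(ev) == 1
    assert ev.loc[0, "onset_date"] == pd.Timestamp("2021-02-10")


def test_suspected_diagnosis_never_qualifies(codes):
    db = _episode_db(suspected=True, course_start="2021-02-11")
    for d in DEFINITIONS.values():
        assert len(detect_severe_infections(db, codes, d)) == 0


def test_test_before_window_fails_original_but_def1_def2_hold(codes):
    """An immunological test before the month preceding admission voids the
    original definition; an antibacterial course starting in hospital still
    yields def1 (onset = admission) and def2 (onset = course start)."""
    db = _episode_db(test_date="2020-12-20", course_start="2021-02-11")
    assert len(detect_severe_infections(db, codes, ORIGINAL)) == 0
    ev1 = detect_severe_infections(db, codes, DEF1)
    assert len(ev1) == 1 and ev1.loc[0, "onset_date"] == pd.Timestamp("2021-02-10")
    ev2 = detect_severe_infections(db, codes, DEF2)
    assert len(ev2) == 1 and ev2.loc[0, "onset_date"] == pd.Timestamp("2021-02-11")


def test_test_on_first_day_of_month_before_admission_qualifies(codes):
    db = _episode_db(test_date="2021-01-01")
    assert len(detect_severe_infections(db, codes, ORIGINAL)) == 1


def test_nonprimary_diagnosis_fails_hospital_definitions(codes):
    db = _episode_db(primary=False, course_start="2021-02-11")
    assert len(detect_severe_infections(db, codes, ORIGINAL)) == 0
    assert len(detect_severe_infections(db, codes, DEF1)) == 0
    assert len(detect_severe_infections(db, codes, DEF2)) == 1


def test_covid_exclusion_def3(codes):
    db = _episode_db(dx_code="U07.1")
    assert len(detect_severe_infections(db, codes, ORIGINAL)) == 1
    assert len(detect_severe_infections(db, codes, DEF3)) == 0


def test_covid_hospitalization_can_qualify_via_other_diagnosis(codes):
    """def3 removes COVID-coded diagnoses, not the whole hospitalization."""
    db = make_db(
        patients=[patient("P1")],
        diagnoses=[
            {"patient_id": "P1", "code": "U07.1", "diagnosis_month": "2021-02",
             "primary_for_hospitalization": True, "linked_hospitalization_id": "H1"},
            {"patient_id": "P1", "code": "A41.0", "diagnosis_month": "2021-02",
             "primary_for_hospitalization": True, "linked_hospitalization_id": "H1"},
        ],
        hospitalizations=[{"hospitalization_id": "H1", "patient_id": "P1",
                           "admission_date": "2021-02-10",
                           "discharge_date": "2021-02-20"}],
        labs=[{"patient_id": "P1", "test_date": "2021-02-10"}],
    )
    assert len(detect_severe_infections(db, codes, DEF3)) == 1


def test_adding_irrelevant_diagnosis_changes_nothing(codes):
    db = _episode_db(course_start="2021-02-11")
    before = {n: detect_severe_infections(db, codes, d)
              for n, d in DEFINITIONS.items()}
    db2 = _episode_db(course_start="2021-02-11")
    extra = pd.concat([db2.diagnoses, pd.DataFrame([{
        "patient_id": "P1", "code": "Z99.9",
        "diagnosis_month": pd.Period("2021-02", freq="M"),
        "suspected": False, "primary_for_hospitalization": False,
        "linked_hospitalization_id": None}])], ignore_index=True)
    db2.diagnoses = extra
    for n, d in DEFINITIONS.items():
        after = detect_severe_infections(db2, codes, d)
        assert len(after) == len(before[n])


@pytest.mark.parametrize("gap_days,expected", [(1, [3, 3]), (2, [8])])
def test_course_merge_rule(codes, gap_days, expected):
    """Records on days 1-3 and 6-8: two 3-day courses at gap 1, one 8-day
    course at gap 2."""
    days = ["2021-03-01", "2021-03-02", "2021-03-03",
            "2021-03-06", "2021-03-07", "2021-03-08"]
    db = make_db(
        patients=[patient("P1")],
        drugs=[drug("P1", "ABX02", d, 500) for d in days],
    )
    courses = build_antibacterial_courses(db, codes, gap_days=gap_days)
    assert courses["duration_days"].tolist() == expected


def test_contiguous_course_duration(codes):
    days = [f"2021-03-{d:02d}" for d in range(5, 12)]
    db = make_db(patients=[patient("P1")],
                 drugs=[drug("P1", "ABX01", d, 500) for d in days])
    courses = build_antibacterial_courses(db, codes)
    assert courses["duration_days"].tolist() == [7]


def test_course_summary_matches_bruteforce(codes):
    """Per-group duration/setting summary equals per-event recomputation."""
    from _oracles import oracle_course_durations

    db, _ = generate_claims_database(SimulationParameters.noisy(n_patients=200, seed=23))
    ev = detect_severe_infections(db, codes, DEF2, first_only=True)
    courses = build_antibacterial_courses(db, codes)
    groups = pd.Series("exposure", index=ev["patient_id"].unique())
    summary = summarize_antibacterial_courses(ev, courses, groups)

    durations = []
    for _, row in ev.iterrows():
        c = courses[courses["course_id"] == row["course_id"]].iloc[0]
        oracle = oracle_course_durations(db, row["patient_id"])
        matching = [d for s, e, d in oracle if s == c["start_date"]]
        assert matching == [c["duration_days"]]
        durations.append(c["duration_days"])
    s = pd.Series(durations, dtype=float)
    exp = summary[summary["group"] == "exposure"].iloc[0]
    assert exp["n"] == len(durations)
    assert exp["mean"] == pytest.approx(s.mean())
    assert exp["median"] == pytest.approx(s.median())
    assert exp["sd"] == pytest.approx(s.std(ddof=1))


def test_definition_nesting_on_seeded_databases(codes):
    for seed in range(5):
        db, _ = generate_claims_database(
            SimulationParameters.noisy(n_patients=250, seed=100 + seed))
        evs = {n: detect_severe_infections(db, codes, d)
               for n, d in DEFINITIONS.items()}
        k1 = set(map(tuple, evs["def1"][["patient_id", "course_id"]].values))
        k2 = set(map(tuple, evs["def2"][["patient_id", "course_id"]].values))
        k3 = set(map(tuple, evs["def3"][["patient_id", "onset_date"]].values))
        ko = set(map(tuple, evs["original"][["patient_id", "onset_date"]].values))
        assert k3 <= ko
        assert k1 <= k2


def test_first_only_returns_earliest_event(codes):
    db = make_db(
        patients=[patient("P1")],
        diagnoses=[
            {"patient_id": "P1", "code": "A41.0", "diagnosis_month": "2021-02",
             "primary_for_hospitalization": True, "linked_hospitalization_id": "H1"},
            {"patient_id": "P1", "code": "J18.9", "diagnosis_month": "2021-05",
             "primary_for_hospitalization": True, "linked_hospitalization_id": "H2"},
        ],
        hospitalizations=[
            {"hospitalization_id": "H1", "patient_id": "P1",
             "admission_date": "2021-02-10", "discharge_date": "2021-02-20"},
            {"hospitalization_id": "H2", "patient_id": "P1",
             "admission_date": "2021-05-05", "discharge_date": "2021-05-10"},
        ],
        labs=[{"patient_id": "P1", "test_date": "2021-02-10"},
              {"patient_id": "P1", "test_date": "2021-05-05"}],
    )
    all_ev = detect_severe_infections(db, codes, ORIGINAL)
    assert len(all_ev) == 2
    first = detect_severe_infections(db, codes, ORIGINAL, first_only=True)
    assert len(first) == 1
    assert first.loc[0, "onset_date"] == pd.Timestamp("2021-02-10")
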