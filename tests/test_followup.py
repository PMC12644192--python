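"""Censoring rules, tie-breaks, and person-time accumulation."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from claimscohort.cohort import build_cohort
from claimscohort.followup import compute_follow_up, person_time_by_group
from claimscohort.outcomes import ORIGINAL, detect_severe_infections

from _helpers import bc_dx, drug, make_db, patient
from _oracles import oracle_follow_up, oracle_original_events

EMPTY_EVENTS = pd.DataFrame(columns=["patient_id", "onset_date"])


def _cohort_db(extra_drugs=(), extra=None):
    db = make_db(
        patients=[patient("P1")],
        diagnoses=[bc_dx("P1", "2020-05")],
        drugs=[drug("P1", "NABP", "2020-05-03", 260)] + list(extra_drugs),
        **(extra or {}),
    )
    cohort = pd.DataFrame({
        "patient_id": ["P1"],
        "index_date": [pd.Timestamp("2020-05-03")],
        "group": ["control"],
    })
    return db, cohort


def test_no_triggers_ends_at_210_days(codes):
    # keep the regimen running past the horizon so only rule 1 applies
    admins = [drug("P1", "NABP", (pd.Timestamp("2020-05-03")
                                  + pd.Timedelta(days=7 * k)).strftime("%Y-%m-%d"), 260)
              for k in range(1, 30)]
    db, cohort = _cohort_db(extra_drugs=admins)
    fu = compute_follow_up(cohort, db, codes, EMPTY_EVENTS)
    assert fu.loc[0, "end_reason"] == "window_210d"
    assert fu.loc[0, "time_days"] == 210
    assert fu.loc[0, "end_date"] == pd.Timestamp("2020-05-03") + pd.Timedelta(days=210)


def test_1200mg_censors_day_before(codes):
    admins = [drug("P1", "NABP", (pd.Timestamp("2020-05-03")
                                  + pd.Timedelta(days=7 * k)).strftime("%Y-%m-%d"), 260)
              for k in range(1, 30)]
    db, cohort = _cohort_db(extra_drugs=admins + [drug("P1", "ATEZ", "2020-08-11", 1200)])
    fu = compute_follow_up(cohort, db, codes, EMPTY_EVENTS)
    assert fu.loc[0, "end_reason"] == "atezolizumab_1200"
    assert fu.loc[0, "time_days"] == 99  # dose at day 100


def test_regimen_end_is_last_dose_plus_grace(codes):
    db, cohort = _cohort_db()
    fu = compute_follow_up(cohort, db, codes, EMPTY_EVENTS, grace_days=28)
    assert fu.loc[0, "end_reason"] == "regimen_end"
    assert fu.loc[0, "time_days"] == 28


def test_outcome_beats_simultaneous_switch(codes):
    """Outcome onset and a censoring trigger on the same day: the event
    counts (tie-break favours the outcome)."""
    onset = pd.Timestamp("2020-05-03") + pd.Timedelta(days=50)
    admins = [drug("P1", "NABP", (pd.Timestamp("2020-05-03")
                                  + pd.Timedelta(days=7 * k)).strftime("%Y-%m-%d"), 260)
              for k in range(1, 30)]
    db, cohort = _cohort_db(
        extra_drugs=admins + [drug("P1", "OANC1", onset.strftime("%Y-%m-%d"), 150)])
    events = pd.DataFrame({"patient_id": ["P1"], "onset_date": [onset]})
    fu = compute_follow_up(cohort, db, codes, events)
    assert fu.loc[0, "end_reason"] == "outcome_onset"
    assert bool(fu.loc[0, "event_indicator"])
    assert fu.loc[0, "time_days"] == 50


def test_trigger_on_index_day_gives_zero_followup_flagged(codes):
    db, cohort = _cohort_db(extra_drugs=[drug("P1", "OANC1", "2020-05-03", 150)])
    fu = compute_follow_up(cohort, db, codes, EMPTY_EVENTS)
    assert fu.loc[0, "time_days"] == 0
    assert bool(fu.loc[0, "zero_followup"])


def test_control_switch_censors_day_before(codes):
    admins = [drug("P1", "NABP", (pd.Timestamp("2020-05-03")
                                  + pd.Timedelta(days=7 * k)).strftime("%Y-%m-%d"), 260)
              for k in range(1, 30)]
    db, cohort = _cohort_db(extra_drugs=admins + [drug("P1", "ATEZ", "2020-07-02", 840)])
    fu = compute_follow_up(cohort, db, codes, EMPTY_EVENTS)
    assert fu.loc[0, "end_reason"] == "regimen_switch"
    assert fu.loc[0, "time_days"] == 59  # switch at day 60


def test_person_years_single_patient(codes):
    admins = [drug("P1", "NABP", (pd.Timestamp("2020-05-03")
                                  + pd.Timedelta(days=7 * k)).strftime("%Y-%m-%d"), 260)
              for k in range(1, 30)]
    db, cohort = _cohort_db(extra_drugs=admins)
    fu = compute_follow_up(cohort, db, codes, EMPTY_EVENTS)
    pt = person_time_by_group(fu)
    assert pt.loc[0, "total_person_years"] == pytest.approx(210 / 365.25)
    assert f"{pt.loc[0, 'total_person_years']:.4f}" == "0.5749"


def test_duplicating_cohort_doubles_person_time(small_perfect_db, codes):
    db, _ = small_perfect_db
    cohort, _ = build_cohort(db, codes)
    events = detect_severe_infections(db, codes, ORIGINAL,
                                      patient_scope=cohort["patient_id"])
    fu = compute_follow_up(cohort, db, codes, events)
    pt1 = person_time_by_group(fu).set_index("group")
    double = pd.concat([fu, fu], ignore_index=True)
    pt2 = person_time_by_group(double).set_index("group")
    for g in pt1.index:
        assert pt2.loc[g, "total_person_years"] == pytest.approx(
            2 * pt1.loc[g, "total_person_years"])
        assert pt2.loc[g, "event_count"] == 2 * pt1.loc[g, "event_count"]


def test_negative_weight_rejected(small_perfect_db, codes):
    db, _ = small_perfect_db
    cohort, _ = build_cohort(db, codes)
    fu = compute_follow_up(cohort, db, codes, EMPTY_EVENTS)
    w = pd.Series(-1.0, index=cohort["patient_id"])
    with pytest.raises(ValueError, match="negative"):
        person_time_by_group(fu, w)


def test_removing_censor_trigger_never_shortens_followup(small_noisy_db, codes):
    db, _ = small_noisy_db
    cohort, _ = build_cohort(db, codes)
    events = detect_severe_infections(db, codes, ORIGINAL,
                                      patient_scope=cohort["patient_id"])
    fu1 = compute_follow_up(cohort, db, codes, events).set_index("patient_id")

    import copy

    db2 = copy.copy(db)
    db2.drugs = db.drugs[~db.drugs["drug_code"].isin(["OANC1", "OANC2"])].reset_index(
        drop=True)
    fu2 = compute_follow_up(cohort, db2, codes, events).set_index("patient_id")
    assert (fu2["time_days"] >= fu1["time_days"]).all()


def test_followup_matches_bruteforce_oracle(codes):
    """End dates and reasons agree with exhaustive per-patient evaluation."""
    from claimscohort.simulate import SimulationParameters, generate_claims_database

    db, _ = generate_claims_database(SimulationParameters.noisy(n_patients=200, seed=31))
    cohort, _ = build_cohort(db, codes)
    events = detect_severe_infections(db, codes, ORIGINAL,
                                      patient_scope=cohort["patient_id"])
    fu = compute_follow_up(cohort, db, codes, events).set_index("patient_id")
    for _, row in cohort.iterrows():
        pid = row["patient_id"]
        onsets = [o for o, _ in oracle_original_events(db, pid)]
        end, reason = oracle_follow_up(db, pid, row["index_date"], row["group"], onsets)
        assert fu.loc[pid, "end_date"] == end, pid
        assert fu.loc[pid, "end_reason"] == reason, pid


@settings(deadline=None, max_examples=25, derandomize=True)
@given(k=st.integers(min_value=1, max_value=209))
def test_1200mg_at_day_k_censors_at_k_minus_1(k):
    from claimscohort.claims import default_code_lists

    codes = default_code_lists()
    admins = [drug("P1", "NABP", (pd.Timestamp("2020-05-03")
                                  + pd.Timedelta(days=7 * j)).strftime("%Y-%m-%d"), 260)
              for j in range(30)]
    dose_day = (pd.Timestamp("2020-05-03") + pd.Timedelta(days=k)).strftime("%Y-%m-%d")
    db = make_db(
        patients=[patient("P1")],
        diagnoses=[bc_dx("P1", "2020-05")],
        drugs=admins + [drug("P1", "ATEZ", dose_day, 1200)],
    )
    cohort = pd.DataFrame({"patient_id": ["P1"],
                           "index_date": [pd.Timestamp("2020-05-03")],
                           "group": ["control"]})
    fu = compute_follow_up(cohort, db, codes, EMPTY_EVENTS)
    assert fu.loc[0, "time_days"] == k - 1
    assert fu.loc[0, "end_reason"] == "atezolizumab_1200"
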