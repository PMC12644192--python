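"""Independent brute-force oracles (plain per-patient loops).

These re-derive cohort eligibility, severe-infection detection, follow-up
end dates, Kaplan-Meier curves, and antibacterial-course summaries directly
from the documented rules, row by row, without using the package's
vectorized implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INFECTION_PREFIXES = ("A4", "B9", "J1", "N39", "U07")
COVID_PREFIXES = ("U07",)
BC_PREFIX = "C50"
HER2_PREFIX = "C50H"
ELIG_LO, ELIG_HI = pd.Timestamp("2019-11-27"), pd.Timestamp("2022-05-31")


def _rows(df, pid):
    return df[df["patient_id"] == pid]


def oracle_original_events(db, pid):
    """Original-definition events for one patient: (onset, hosp_id) list."""
    out = []
    for _, h in _rows(db.hospitalizations, pid).iterrows():
        dxs = _rows(db.diagnoses, pid)
        qual = False
        for _, d in dxs.iterrows():
            if (str(d["code"]).startswith(INFECTION_PREFIXES)
                    and not d["suspected"] and d["primary_for_hospitalization"]
                    and d["linked_hospitalization_id"] == h["hospitalization_id"]):
                qual = True
        if not qual:
            continue
        month_before_start = (pd.Period(h["admission_date"], freq="M") - 1).start_time
        test_ok = False
        for _, lab in _rows(db.labs, pid).iterrows():
            if (lab["category"] == "immunological_infection"
                    and month_before_start <= lab["test_date"] <= h["discharge_date"]):
                test_ok = True
        if test_ok:
            out.append((h["admission_date"], h["hospitalization_id"]))
    return sorted(out)


def oracle_candidate(db, pid, window_days=28):
    """(index_date, group) for one patient, or None."""
    admins = _rows(db.drugs, pid)
    study = admins[
        ((admins["drug_code"] == "NABP"))
        | ((admins["drug_code"] == "ATEZ") & (admins["dose_mg"] == 840.0))]
    if not len(study):
        return None
    index = study["administration_date"].min()
    in_w = study[study["administration_date"] <= index + pd.Timedelta(days=window_days)]
    has_atezo = ((in_w["drug_code"] == "ATEZ") & (in_w["dose_mg"] == 840.0)).any()
    has_nabp = (in_w["drug_code"] == "NABP").any()
    if not has_nabp:
        return None
    if not (ELIG_LO <= index <= ELIG_HI):
        return None
    bc_ok = False
    for _, d in _rows(db.diagnoses, pid).iterrows():
        if (str(d["code"]).startswith(BC_PREFIX) and not d["suspected"]
                and d["diagnosis_month"] == pd.Period(index, freq="M")):
            bc_ok = True
    if not bc_ok:
        return None
    return index, ("exposure" if has_atezo else "control")


def oracle_exclusions(db, pid, index):
    """Which exclusion criteria (in order) the patient trips."""
    tripped = []
    pat = _rows(db.patients, pid).iloc[0]
    lookback = (index - pat["first_record_date"]).days
    path = any(
        (p["category"] == "pathological_diagnosis") and p["procedure_date"] <= index
        for _, p in _rows(db.procedures, pid).iterrows())
    if lookback <= 89 and not path:
        tripped.append("excl_short_lookback")
    drugs = _rows(db.drugs, pid)
    prior_sd = any(
        (d["drug_code"] in ("ATEZ", "NABP")) and d["administration_date"] < index
        for _, d in drugs.iterrows())
    if prior_sd:
        tripped.append("excl_prior_study_drug")
    events = oracle_original_events(db, pid)
    if any(index - pd.Timedelta(days=30) <= onset <= index - pd.Timedelta(days=1)
           for onset, _ in events):
        tripped.append("excl_preindex_infection")
    her2 = any(
        str(d["code"]).startswith(HER2_PREFIX)
        and d["diagnosis_month"] <= pd.Period(index, freq="M")
        for _, d in _rows(db.diagnoses, pid).iterrows())
    if her2:
        tripped.append("excl_her2")
    for code, name in [("ADJC1", "excl_adjuvant_chemo"), ("OREG1", "excl_other_regimen")]:
        if any((d["drug_code"] == code) and d["administration_date"] < index
               for _, d in drugs.iterrows()):
            tripped.append(name)
    if index == pat["last_visit_date"]:
        tripped.append("excl_index_last_visit")
    return tripped


def oracle_attrition(db, window_days=28):
    """Full brute-force attrition: candidate count then sequential removals."""
    order = ["excl_short_lookback", "excl_prior_study_drug", "excl_preindex_infection",
             "excl_her2", "excl_adjuvant_chemo", "excl_other_regimen",
             "excl_index_last_visit"]
    cands = {}
    for pid in db.patients["patient_id"]:
        res = oracle_candidate(db, pid, window_days)
        if res is not None:
            cands[pid] = res
    surviving = dict(cands)
    counts = [("candidates", 0, len(surviving))]
    for crit in order:
        removed = [pid for pid, (idx, _) in surviving.items()
                   if crit in oracle_exclusions(db, pid, idx)]
        for pid in removed:
            surviving.pop(pid)
        counts.append((crit, len(removed), len(surviving)))
    return counts, surviving


def oracle_follow_up(db, pid, index, group, onset_dates,
                     grace_days=28, window_days=28, horizon=210):
    """(end_date, end_reason) for one patient by exhaustive rule evaluation."""
    cands = {}
    cands["window_210d"] = index + pd.Timedelta(days=horizon)
    onsets = [o for o in onset_dates
              if index <= o <= index + pd.Timedelta(days=horizon)]
    if onsets:
        cands["outcome_onset"] = min(onsets)
    drugs = _rows(db.drugs, pid)
    regimen = []
    d1200, switch, other = [], [], []
    for _, d in drugs.iterrows():
        dt = d["administration_date"]
        if dt < index:
            continue
        if d["drug_code"] == "NABP":
            regimen.append(dt)
        if d["drug_code"] == "ATEZ" and d["dose_mg"] == 840.0:
            if group == "exposure":
                regimen.append(dt)
            elif dt > index + pd.Timedelta(days=window_days):
                switch.append(dt)
        if d["drug_code"] == "ATEZ" and d["dose_mg"] == 1200.0:
            d1200.append(dt)
        if d["drug_code"] in ("OANC1", "OANC2"):
            other.append(dt)
    if regimen:
        cands["regimen_end"] = max(regimen) + pd.Timedelta(days=grace_days)
    if d1200:
        cands["atezolizumab_1200"] = min(d1200)
    if switch:
        cands["regimen_switch"] = min(switch)
    if other:
        cands["other_anticancer"] = min(other)
    end = min(cands.values())
    priority = ["outcome_onset", "window_210d", "atezolizumab_1200",
                "regimen_switch", "other_anticancer", "regimen_end"]
    reason = next(r for r in priority if cands.get(r) == end)
    if reason in ("atezolizumab_1200", "regimen_switch", "other_anticancer"):
        end = end - pd.Timedelta(days=1)
    if end < index:
        end = index
    return end, reason


def oracle_km(times, events, weights=None):
    """Product-limit curve as a list of (time, survival) at event times."""
    times = list(times)
    events = list(events)
    weights = [1.0] * len(times) if weights is None else list(weights)
    out = [(0.0, 1.0)]
    surv = 1.0
    for tj in sorted({t for t, e in zip(times, events) if e}):
        n_risk = sum(w for t, w in zip(times, weights) if t >= tj)
        d = sum(w for t, e, w in zip(times, events, weights) if e and t == tj)
        surv *= 1.0 - d / n_risk
        out.append((float(tj), surv))
    return out


def oracle_course_durations(db, pid, gap_days=1):
    """Antibacterial course (start, end, duration) list for one patient."""
    abx = _rows(db.drugs, pid)
    abx = abx[abx["drug_code"].str.startswith("ABX")
              & (abx["route"] == "intravenous")]
    days = sorted(abx["administration_date"].unique())
    courses = []
    for d in days:
        if courses and (d - courses[-1][1]).days <= gap_days + 1:
            courses[-1][1] = d
        else:
            courses.append([d, d])
    return [(s, e, (e - s).days + 1) for s, e in courses]
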