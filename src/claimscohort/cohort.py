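"""Cohort construction: index date, exposure/control assignment, exclusions.

The index date is the first administration of either study drug
(combination partner at the TNBC dose of 840 mg, or the taxane), whichever
occurred earlier.  A patient is *exposure* when both drugs appear within
``combination_window_days`` of the index, *control* when only the taxane
does.  Candidates must have a confirmed breast-cancer diagnosis in the
index month and an index date inside the eligibility window.

Seven exclusion criteria are then applied sequentially, producing a
CONSORT-style attrition table.
"""

from __future__ import annotations

import pandas as pd

from .claims import ClaimsDatabase, CodeLists, match_codes
from .outcomes import ORIGINAL, detect_severe_infections

__all__ = [
    "assign_index_and_group",
    "apply_exclusions",
    "build_cohort",
    "EXCLUSION_LABELS",
]

DEFAULT_ELIGIBILITY_WINDOW = ("2019-11-27", "2022-05-31")

EXCLUSION_LABELS = {
    "excl_short_lookback": "Data record <=89 days before index without pathological diagnosis",
    "excl_prior_study_drug": "History of study regimen treatment",
    "excl_preindex_infection": "Severe infection within 30 days before index",
    "excl_her2": "HER2-positive breast cancer",
    "excl_adjuvant_chemo": "History of adjuvant/neoadjuvant chemotherapy",
    "excl_other_regimen": "History of other cancer regimens",
    "excl_index_last_visit": "Index date equal to the last visit",
}


def _study_drug_admins(db: ClaimsDatabase, codes: CodeLists) -> pd.DataFrame:
    """Study-drug administrations: 840 mg combination doses and any taxane dose."""
    d = db.drugs
    atez = match_codes(d["drug_code"], codes.study_drug["atezolizumab"])
    nabp = match_codes(d["drug_code"], codes.study_drug["nab_paclitaxel"])
    out = d.loc[(atez & (d["dose_mg"] == 840.0)) | nabp,
                ["patient_id", "drug_code", "administration_date", "dose_mg"]].copy()
    out["is_atezo"] = match_codes(out["drug_code"], codes.study_drug["atezolizumab"]).to_numpy()
    return out


def assign_index_and_group(
    db: ClaimsDatabase,
    codes: CodeLists,
    combination_window_days: int = 28,
    eligibility_window: tuple[str, str] = DEFAULT_ELIGIBILITY_WINDOW,
) -> pd.DataFrame:
    """Identify candidate patients with index date and treatment group.

    Returns a DataFrame with ``patient_id``, ``index_date``, ``group``
    (``exposure``/``control``) and ``lookback_days``, sorted by patient id.
    Patients whose only qualifying drug is the 840 mg combination partner
    (no taxane within the window) receive neither study regimen and are not
    candidates; neither are patients on the 1200 mg dose alone.
    """
    admins = _study_drug_admins(db, codes)
    if not len(admins):
        return pd.DataFrame(
            columns=["patient_id", "index_date", "group", "lookback_days"])
    index = admins.groupby("patient_id")["administration_date"].min().rename("index_date")
    admins = admins.join(index, on="patient_id")
    in_window = admins["administration_date"] <= admins["index_date"] + pd.Timedelta(
        days=combination_window_days)
    flags = (
        admins[in_window]
        .groupby("patient_id")
        .agg(has_atezo=("is_atezo", "any"),
             has_nabp=("is_atezo", lambda s: (~s).any()))
    )
    cand = flags.join(index)
    cand = cand[cand["has_nabp"]]
    cand["group"] = cand["has_atezo"].map({True: "exposure", False: "control"})

    lo, hi = (pd.Timestamp(d) for d in eligibility_window)
    cand = cand[(cand["index_date"] >= lo) & (cand["index_date"] <= hi)]

    # confirmed breast-cancer diagnosis in the index month
    dx = db.diagnoses
    bc = dx[match_codes(dx["code"], codes.breast_cancer) & ~dx["suspected"]]
    idx_month = pd.PeriodIndex(cand["index_date"], freq="M")
    key = cand.index.astype(str) + "|" + idx_month.astype(str)
    bc_key = set(bc["patient_id"].astype(str) + "|" + bc["diagnosis_month"].astype(str))
    cand = cand[pd.Series(key, index=cand.index).isin(bc_key)]

    cand = cand.reset_index().rename(columns={"index": "patient_id"})
    first = db.patients.set_index("patient_id")["first_record_date"]
    cand["lookback_days"] = (
        cand["index_date"] - cand["patient_id"].map(first)).dt.days
    return (cand[["patient_id", "index_date", "group", "lookback_days"]]
            .sort_values("patient_id").reset_index(drop=True))


def _exclusion_flags(
    candidates: pd.DataFrame,
    db: ClaimsDatabase,
    codes: CodeLists,
    gap_days: int = 1,
) -> pd.DataFrame:
    """Evaluate each exclusion criterion independently for every candidate."""
    c = candidates.set_index("patient_id")
    idx = c["index_date"]
    flags = pd.DataFrame(index=c.index)

    # (a) short lookback without pathological diagnosis
    procs = db.procedures
    path = procs[procs["category"] == "pathological_diagnosis"]
    path_ok = (
        path.join(idx, on="patient_id")
        .pipe(lambda d: d[d["procedure_date"] <= d["index_date"]])
        .groupby("patient_id").size().reindex(c.index, fill_value=0) > 0
    )
    flags["excl_short_lookback"] = (c["lookback_days"] <= 89) & ~path_ok

    # (b) any study-drug administration strictly before index (any dose)
    d = db.drugs
    study = d[
        match_codes(d["drug_code"], codes.study_drug["atezolizumab"])
        | match_codes(d["drug_code"], codes.study_drug["nab_paclitaxel"])
    ].join(idx, on="patient_id")
    prior_sd = (study["administration_date"] < study["index_date"]).groupby(
        study["patient_id"]).any().reindex(c.index, fill_value=False)
    flags["excl_prior_study_drug"] = prior_sd

    # (c) severe infection (original definition) onset in [index-30 d, index-1 d]
    events = detect_severe_infections(
        db, codes, ORIGINAL, patient_scope=c.index, first_only=False, gap_days=gap_days)
    if len(events):
        ev = events.join(idx, on="patient_id")
        hit = (
            (ev["onset_date"] >= ev["index_date"] - pd.Timedelta(days=30))
            & (ev["onset_date"] <= ev["index_date"] - pd.Timedelta(days=1))
        ).groupby(ev["patient_id"]).any()
        flags["excl_preindex_infection"] = hit.reindex(c.index, fill_value=False)
    else:
        flags["excl_preindex_infection"] = False

    # (d) HER2-positive code before or at index (month granularity)
    dx = db.diagnoses
    her2 = dx[match_codes(dx["code"], codes.her2_positive)].join(idx, on="patient_id")
    if len(her2):
        hit = (
            her2["diagnosis_month"] <= pd.PeriodIndex(her2["index_date"], freq="M")
        ).groupby(her2["patient_id"]).any()
        flags["excl_her2"] = hit.reindex(c.index, fill_value=False)
    else:
        flags["excl_her2"] = False

    # (e)/(f) history of adjuvant chemo / other regimens, strictly before index
    for col, code_list in [
        ("excl_adjuvant_chemo", codes.adjuvant_chemo),
        ("excl_other_regimen", codes.other_regimen),
    ]:
        hist = d[match_codes(d["drug_code"], code_list)].join(idx, on="patient_id")
        if len(hist):
            hit = (hist["administration_date"] < hist["index_date"]).groupby(
                hist["patient_id"]).any()
            flags[col] = hit.reindex(c.index, fill_value=False)
        else:
            flags[col] = False

    # (g) index date equal to the last visit
    last = db.patients.set_index("patient_id")["last_visit_date"]
    flags["excl_index_last_visit"] = idx == c.index.map(last)

    return flags


def apply_exclusions(
    candidates: pd.DataFrame,
    db: ClaimsDatabase,
    codes: CodeLists,
    gap_days: int = 1,
    order_independent_counts: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the exclusion criteria sequentially.

    Returns ``(retained, attrition)``: the retained cohort (with one
    boolean eligibility flag column per criterion) and the attrition table
    ``(criterion, removed, remaining)``.  Counts are order-dependent
    (each row counts patients removed among those surviving the previous
    steps); with ``order_independent_counts`` an extra column reports how
    many candidates trip each criterion regardless of order.
    """
    if not len(candidates):
        attr = pd.DataFrame(
            [("candidates", 0, 0)], columns=["criterion", "removed", "remaining"])
        return candidates.copy(), attr

    flags = _exclusion_flags(candidates, db, codes, gap_days=gap_days)
    rows = [{"criterion": "candidates", "removed": 0, "remaining": len(candidates)}]
    surviving = pd.Series(True, index=flags.index)
    for col, label in EXCLUSION_LABELS.items():
        removed = int((surviving & flags[col]).sum())
        surviving &= ~flags[col]
        row = {"criterion": label, "removed": removed, "remaining": int(surviving.sum())}
        if order_independent_counts:
            row["flagged_any_order"] = int(flags[col].sum())
        rows.append(row)
    attrition = pd.DataFrame(rows)

    out = candidates.set_index("patient_id").join(flags)
    retained = out[surviving].reset_index()
    out = out.reset_index()
    retained.attrs["all_candidates_with_flags"] = out
    return retained, attrition


def build_cohort(
    db: ClaimsDatabase,
    codes: CodeLists,
    combination_window_days: int = 28,
    eligibility_window: tuple[str, str] = DEFAULT_ELIGIBILITY_WINDOW,
    gap_days: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: candidates then exclusions."""
    candidates = assign_index_and_group(
        db, codes, combination_window_days, eligibility_window)
    return apply_exclusions(candidates, db, codes, gap_days=gap_days)
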