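"""Observation intervals under the six censoring rules, and person-time.

Follow-up runs from the index date (day 0) until the earliest of:

1. 210 days after the index date (the administrative horizon);
2. onset of a qualifying severe infection (the only end reason counted
   as an event);
3. end of the study regimen, operationalized as the last study-drug
   administration plus a grace period of one treatment cycle;
4. the day before a 1200 mg dose of the combination partner (a dose
   approved for other indications, flagging a change of primary disease);
5. the day before a control patient starts the combination partner after
   the combination window (regimen switch);
6. the day before any other anticancer drug.

Ties are broken in the deterministic priority order
outcome > horizon > 1200 mg dose > switch > other anticancer > regimen
end, so an outcome on the same day as a censoring trigger still counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .claims import ClaimsDatabase, CodeLists, match_codes

__all__ = ["compute_follow_up", "person_time_by_group", "END_REASON_PRIORITY"]

#: tie-break priority (highest first)
END_REASON_PRIORITY = [
    "outcome_onset",
    "window_210d",
    "atezolizumab_1200",
    "regimen_switch",
    "other_anticancer",
    "regimen_end",
]


def compute_follow_up(
    cohort: pd.DataFrame,
    db: ClaimsDatabase,
    codes: CodeLists,
    events: pd.DataFrame,
    grace_days: int = 28,
    combination_window_days: int = 28,
    horizon_days: int = 210,
) -> pd.DataFrame:
    """Compute each patient's observation end date and end reason.

    ``events`` is an event table from the outcome engine (all events or
    first events; the earliest onset in ``[index, index + horizon]`` is
    used).  Returns one row per cohort patient with ``end_date``,
    ``end_reason``, ``event_indicator``, ``time_days`` and a
    ``zero_followup`` flag for patients whose earliest censoring trigger
    precedes the index date (retained with zero person-time).
    """
    c = cohort.set_index("patient_id")
    idx = c["index_date"]
    n = len(c)
    cand = pd.DataFrame(index=c.index)
    cand["window_210d"] = idx + pd.Timedelta(days=horizon_days)

    # rule 2: earliest qualifying outcome onset in [index, index + horizon]
    if len(events):
        ev = events.join(idx, on="patient_id")
        ev = ev[(ev["onset_date"] >= ev["index_date"])
                & (ev["onset_date"] <= ev["index_date"] + pd.Timedelta(days=horizon_days))]
        cand["outcome_onset"] = ev.groupby("patient_id")["onset_date"].min()
    else:
        cand["outcome_onset"] = pd.NaT

    d = db.drugs.join(idx, on="patient_id").dropna(subset=["index_date"])
    atez = match_codes(d["drug_code"], codes.study_drug["atezolizumab"])
    nabp = match_codes(d["drug_code"], codes.study_drug["nab_paclitaxel"])
    post = d["administration_date"] >= d["index_date"]

    # rule 3: regimen end = last study-drug administration + grace.
    # Exposure regimens comprise both drugs (840 mg partner doses); control
    # regimens the taxane alone — a control patient's later partner dose is a
    # switch (rule 5), not a continuation.
    group = c["group"]
    is_exposure = d["patient_id"].map(group).eq("exposure")
    regimen_drug = post & (nabp | (atez & (d["dose_mg"] == 840.0) & is_exposure))
    last_admin = d.loc[regimen_drug].groupby("patient_id")["administration_date"].max()
    cand["regimen_end"] = last_admin.reindex(c.index) + pd.Timedelta(days=grace_days)

    # rules 4-6 censor at the day BEFORE the trigger prescription.  The
    # minimum is taken over trigger *record* dates and the one-day
    # subtraction applied only when such a rule wins, so an outcome on the
    # same day as a censoring prescription still counts as an event.
    d1200 = d[atez & (d["dose_mg"] == 1200.0) & post]
    cand["atezolizumab_1200"] = (
        d1200.groupby("patient_id")["administration_date"].min().reindex(c.index))

    # rule 5: control switch = first 840 mg partner dose after the window
    sw = d[atez & (d["dose_mg"] == 840.0) & ~is_exposure
           & (d["administration_date"] > d["index_date"]
              + pd.Timedelta(days=combination_window_days))]
    cand["regimen_switch"] = (
        sw.groupby("patient_id")["administration_date"].min().reindex(c.index))

    # rule 6: first other-anticancer prescription on/after index
    oanc = d[match_codes(d["drug_code"], codes.other_anticancer) & post]
    cand["other_anticancer"] = (
        oanc.groupby("patient_id")["administration_date"].min().reindex(c.index))

    cand = cand[END_REASON_PRIORITY]
    end = cand.min(axis=1)
    # tie-break: first reason (in priority order) attaining the minimum
    reason = pd.Series(
        np.array(END_REASON_PRIORITY, dtype=object)[
            cand.eq(end, axis=0).to_numpy().argmax(axis=1)],
        index=c.index, name="end_reason")

    day_before = reason.isin(["atezolizumab_1200", "regimen_switch", "other_anticancer"])
    end = end.where(~day_before, end - pd.Timedelta(days=1))

    zero = end < idx
    end = end.where(~zero, idx)

    out = pd.DataFrame({
        "patient_id": c.index,
        "index_date": idx.to_numpy(),
        "group": c["group"].to_numpy(),
        "end_date": end.to_numpy(),
        "end_reason": reason.to_numpy(),
        "event_indicator": (reason == "outcome_onset").to_numpy(),
        "time_days": (end - idx).dt.days.to_numpy(),
        "zero_followup": zero.to_numpy(),
    }).reset_index(drop=True)
    assert (out["time_days"] >= 0).all() and (out["time_days"] <= horizon_days).all()
    return out


def person_time_by_group(
    followups: pd.DataFrame,
    weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Accumulate (weighted) events and person-years per group.

    Person-years = Σ wᵢ·daysᵢ / 365.25; events = Σ wᵢ·eventᵢ.  Also returns
    Σ wᵢ²·eventᵢ, the variance term used by weighted rate CIs.
    """
    if weights is None:
        w = pd.Series(1.0, index=followups.index)
    else:
        w = followups["patient_id"].map(weights).astype(float)
        if (w < 0).any():
            raise ValueError("negative weight")
    f = followups.assign(_w=w.to_numpy())
    rows = []
    for group, sub in f.groupby("group"):
        e = sub["event_indicator"].astype(float)
        rows.append({
            "group": group,
            "total_person_years": float((sub["_w"] * sub["time_days"]).sum() / 365.25),
            "event_count": float((sub["_w"] * e).sum()),
            "event_count_w2": float((sub["_w"] ** 2 * e).sum()),
            "n": len(sub),
            "weighted_n": float(sub["_w"].sum()),
        })
    return pd.DataFrame(rows)
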