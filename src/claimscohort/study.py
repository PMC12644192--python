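"""End-to-end study orchestration.

``run_study`` executes the full analysis on a claims database: cohort
construction with attrition, covariate derivation, propensity fitting and
SMR weighting (with optional overlap trimming), outcome detection under
all four definitions, follow-up and person-time, incidence rates and rate
ratios (unadjusted and weighted, plus the trimmed sensitivity row),
Kaplan–Meier curves, and the post hoc clinical-event and
antibacterial-course summaries.  Deterministic given its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from pydantic import BaseModel

from .claims import ClaimsDatabase, CodeLists, default_code_lists
from .cohort import DEFAULT_ELIGIBILITY_WINDOW, build_cohort
from .estimation import (
    RateRatioEstimate,
    WeightedRateEstimate,
    clinical_event_summary,
    km_curve,
    rate_from_person_time,
    rate_ratio,
)
from .followup import compute_follow_up, person_time_by_group
from .outcomes import (
    DEFINITIONS,
    build_antibacterial_courses,
    detect_severe_infections,
    first_events,
    summarize_antibacterial_courses,
)
from .weighting import (
    balance_table,
    derive_covariates,
    fit_propensity_model,
    smr_weights,
    trim_by_overlap,
    unadjusted_weights,
)

__all__ = ["StudyConfig", "StudyReport", "run_study", "analyze_definition"]


class StudyConfig(BaseModel):
    """Analysis configuration (defaults reproduce the primary design)."""

    combination_window_days: int = 28
    grace_days: int = 28
    gap_days: int = 1
    def2_lookback_days: int = 7
    steroid_window_days: int = 90
    covid_season_start: str = "2020-04-01"
    eligibility_window: tuple[str, str] = DEFAULT_ELIGIBILITY_WINDOW
    horizon_days: int = 210
    alpha: float = 0.05
    continuity: float = 0.5
    trimming: bool = True
    definitions: tuple[str, ...] = ("original", "def1", "def2", "def3")


@dataclass
class StudyReport:
    attrition: pd.DataFrame
    cohort: pd.DataFrame
    covariates: pd.DataFrame
    propensity: object
    weights: pd.Series
    balance: pd.DataFrame
    rates: pd.DataFrame
    km: dict[tuple[str, str, str], pd.DataFrame]
    followups: dict[str, pd.DataFrame]
    posthoc_clinical: pd.DataFrame
    posthoc_antibacterial: pd.DataFrame
    trimmed_patient_ids: list[str]
    log: list[str] = field(default_factory=list)


def _rate_rows(
    definition: str,
    adjustment: str,
    pt: pd.DataFrame,
    alpha: float,
    continuity: float,
) -> list[dict]:
    ests: dict[str, WeightedRateEstimate] = {}
    for _, row in pt.iterrows():
        ests[row["group"]] = rate_from_person_time(row, alpha=alpha)
    rows = []
    for group in ("exposure", "control"):
        e = ests[group]
        rows.append({
            "definition": definition, "adjustment": adjustment,
            "measure": f"rate_{group}", "value": e.rate,
            "ci_low": e.ci_low, "ci_high": e.ci_high,
            "events": e.events, "person_years": e.person_years,
        })
    rr: RateRatioEstimate = rate_ratio(
        ests["exposure"], ests["control"], continuity=continuity, alpha=alpha)
    rows.append({
        "definition": definition, "adjustment": adjustment, "measure": "irr",
        "value": rr.irr, "ci_low": rr.ci_low, "ci_high": rr.ci_high,
        "events": float("nan"), "person_years": float("nan"),
    })
    return rows


def analyze_definition(
    db: ClaimsDatabase,
    codes: CodeLists,
    cohort: pd.DataFrame,
    weights: pd.Series,
    definition_name: str,
    config: StudyConfig,
    courses: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Events, follow-ups, and Table-2-style rate rows for one definition."""
    definition = DEFINITIONS[definition_name]
    events = detect_severe_infections(
        db, codes, definition, patient_scope=cohort["patient_id"],
        gap_days=config.gap_days, def2_lookback_days=config.def2_lookback_days,
        courses=courses)
    fu = compute_follow_up(
        cohort, db, codes, events, grace_days=config.grace_days,
        combination_window_days=config.combination_window_days,
        horizon_days=config.horizon_days)
    rows = _rate_rows(definition_name, "unadjusted", person_time_by_group(fu),
                      config.alpha, config.continuity)
    rows += _rate_rows(definition_name, "smrw", person_time_by_group(fu, weights),
                       config.alpha, config.continuity)
    return events, fu, rows


def run_study(
    db: ClaimsDatabase,
    codes: CodeLists | None = None,
    config: StudyConfig | None = None,
) -> StudyReport:
    """Execute the full study pipeline and assemble the report."""
    codes = codes if codes is not None else default_code_lists()
    config = config if config is not None else StudyConfig()
    log: list[str] = []

    cohort, attrition = build_cohort(
        db, codes, config.combination_window_days, config.eligibility_window,
        gap_days=config.gap_days)
    log.append(f"cohort: {len(cohort)} patients retained "
               f"({(cohort['group'] == 'exposure').sum()} exposure / "
               f"{(cohort['group'] == 'control').sum()} control)")
    if not len(cohort):
        raise ValueError("empty cohort: no eligible patients")

    covariates = derive_covariates(
        cohort, db, codes, covid_season_start=config.covid_season_start,
        steroid_window_days=config.steroid_window_days)
    treatment = cohort.set_index("patient_id")["group"].eq("exposure")
    ps = fit_propensity_model(covariates, treatment)
    wa = smr_weights(ps, treatment)
    log.append(f"SMRW weighted N: exposure {wa.weighted_n['exposure']:.1f}, "
               f"control {wa.weighted_n['control']:.1f}; "
               f"max control weight {wa.weights[~treatment].max():.2f}")
    balance = balance_table(
        covariates, treatment, wa.weights,
        include=[c for c in covariates.columns])

    courses = build_antibacterial_courses(
        db, codes, config.gap_days, patient_scope=cohort["patient_id"])

    rate_rows: list[dict] = []
    km: dict[tuple[str, str, str], pd.DataFrame] = {}
    followups: dict[str, pd.DataFrame] = {}
    events_by_def: dict[str, pd.DataFrame] = {}
    for name in config.definitions:
        events, fu, rows = analyze_definition(
            db, codes, cohort, wa.weights, name, config, courses=courses)
        events_by_def[name] = events
        followups[name] = fu
        rate_rows += rows
        for adjustment, w in (("unadjusted", None), ("smrw", wa.weights)):
            for group, sub in fu.groupby("group"):
                wg = None if w is None else w.reindex(sub["patient_id"]).to_numpy()
                km[(name, adjustment, group)] = km_curve(
                    sub["time_days"], sub["event_indicator"], wg)

    trimmed_ids: list[str] = []
    if config.trimming:
        keep = trim_by_overlap(ps, treatment)
        trimmed_ids = list(keep.index[keep])
        log.append(f"trimming: {int((~keep).sum())} patients outside overlap removed")
        sub_cohort = cohort[cohort["patient_id"].isin(trimmed_ids)]
        name = config.definitions[0]
        fu_t = compute_follow_up(
            sub_cohort, db, codes, events_by_def[name],
            grace_days=config.grace_days,
            combination_window_days=config.combination_window_days,
            horizon_days=config.horizon_days)
        pt = person_time_by_group(fu_t, wa.weights)
        rate_rows += _rate_rows(name, "trimmed_smrw", pt, config.alpha,
                                config.continuity)

    rates = pd.DataFrame(rate_rows)

    first_def = config.definitions[0]
    fu0 = followups[first_def]
    posthoc_clinical = clinical_event_summary(fu0, db, codes, wa.weights)
    groups = cohort.set_index("patient_id")["group"]
    if "def2" in events_by_def and len(events_by_def["def2"]):
        def2_first = first_events(events_by_def["def2"], cohort, config.horizon_days)
        posthoc_abx = summarize_antibacterial_courses(def2_first, courses, groups)
    else:
        posthoc_abx = pd.DataFrame()

    return StudyReport(
        attrition=attrition, cohort=cohort, covariates=covariates, propensity=ps,
        weights=wa.weights, balance=balance, rates=rates, km=km,
        followups=followups, posthoc_clinical=posthoc_clinical,
        posthoc_antibacterial=posthoc_abx, trimmed_patient_ids=trimmed_ids, log=log)
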