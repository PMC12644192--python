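"""Seeded synthetic claims-database generator with known ground truth.

Emulates a hospital-based administrative claims extract for an
active-comparator cohort study of severe infection risk under an
immunotherapy+taxane combination versus taxane monotherapy:

* 13 baseline covariates drawn from configurable distributions
  (calibrated by default to the study population's published summaries);
* treatment assigned by a logistic model on the covariates, with the
  intercept solved numerically so the expected treated fraction hits a
  target;
* a single exponential severe-infection time per patient whose hazard is
  ``baseline_rate × exp(β·(x − x̄)) × RR^treated`` — at most the first
  event matters because observation ends at onset, so recurrent events
  are not simulated;
* claims records emitted from the latent history through configurable
  *phenotype emission* probabilities (hospitalization, primary-reason
  diagnosis, immunological test, IV antibacterial course), plus optional
  background noise records, so the claims-based outcome definitions can
  be degraded deliberately;
* deliberate small subpopulations that trigger each eligibility
  exclusion, so attrition logic is exercised end to end.

Every random draw comes from a named child stream of the master seed, so
adding noise records does not perturb covariate draws, and two calls with
the same parameters produce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.optimize import brentq
from scipy.special import expit

from .claims import ClaimsDatabase

__all__ = [
    "SimulationParameters",
    "GroundTruth",
    "ExpectedSummaries",
    "generate_claims_database",
    "expected_summaries",
]

_EPOCH = np.datetime64("1970-01-01", "D")

#: the 13 baseline covariates, in canonical order
COVARIATE_NAMES = [
    "age_years",
    "bc_duration_months",
    "covid_season",
    "renal_impairment",
    "hepatic_impairment",
    "lymph_node_metastasis",
    "diabetes",
    "cci_score",
    "prior_bc_surgery",
    "prior_non_bc_surgery",
    "prior_radiotherapy",
    "prior_anticancer",
    "steroid_use",
]

#: centering constants for continuous covariates in the logit/log-hazard models
_CENTERS = {"age_years": 59.2, "bc_duration_months": 24.9, "cci_score": 6.65}


def _day(date: str | pd.Timestamp) -> int:
    return (pd.Timestamp(date) - pd.Timestamp(_EPOCH)).days


def _dates(day_numbers: np.ndarray) -> np.ndarray:
    return _EPOCH + day_numbers.astype("timedelta64[D]")


class CovariateDistributions(BaseModel):
    """Marginal distributions of the 13 baseline covariates (independent)."""

    age_mean: float = 59.2
    age_sd: float = 12.65
    bc_duration_mean: float = 24.9
    bc_duration_sd: float = 26.7
    p_renal: float = 0.106
    p_hepatic: float = 0.298
    p_lymph_node: float = 0.395
    p_diabetes: float = 0.147
    cci_mean: float = 6.65
    cci_sd: float = 3.3
    p_prior_bc_surgery: float = 0.041
    p_prior_non_bc_surgery: float = 0.548
    p_prior_radiotherapy: float = 0.286
    p_prior_anticancer: float = 0.794
    p_steroid: float = 0.481
    covid_season_fraction: float = 0.86
    female_fraction: float = 0.998


class PhenotypeEmission(BaseModel):
    """Probability that a true infection event emits each claims component."""

    p_hospitalization: float = 1.0
    p_primary_diagnosis: float = 1.0
    p_immunological_test: float = 1.0
    p_iv_antibacterial: float = 1.0


class BackgroundRates(BaseModel):
    """Per-person-year rates of non-infection noise records."""

    hospitalization: float = 0.0
    immunological_test: float = 0.0
    antibacterial_course: float = 0.0
    noninfection_diagnosis: float = 0.0


class CensoringTriggers(BaseModel):
    """Fractions of patients receiving post-index censoring-trigger drugs."""

    p_atezolizumab_1200: float = 0.015
    p_other_anticancer: float = 0.02
    p_control_switch: float = 0.02
    trigger_day_min: int = 30
    trigger_day_max: int = 200


class PatientMix(BaseModel):
    """Fractions of deliberately atypical / exclusion-triggering patients."""

    p_no_study_drug: float = 0.03
    p_atezo1200_only: float = 0.01
    p_short_lookback: float = 0.03
    p_short_lookback_with_pathology: float = 0.3
    p_prior_study_drug: float = 0.01
    p_her2: float = 0.03
    p_adjuvant_chemo: float = 0.02
    p_other_regimen: float = 0.02
    p_preindex_infection: float = 0.02
    p_index_equals_last_visit: float = 0.01
    p_pathological_dx: float = 0.95


class RegimenDuration(BaseModel):
    """Weekly-administration regimen length in weeks (truncated geometric)."""

    mean_weeks: float = 16.0
    max_weeks: int = 30


class SimulationParameters(BaseModel):
    """Full parameter block for :func:`generate_claims_database`."""

    n_patients: int = 5000
    seed: int = 0
    treated_fraction_target: float = 0.5
    data_period: tuple[str, str] = ("2012-01-01", "2022-12-31")
    eligibility_window: tuple[str, str] = ("2019-11-27", "2022-05-31")
    covid_season_start: str = "2020-04-01"
    covariates: CovariateDistributions = Field(default_factory=CovariateDistributions)
    treatment_logit_coefficients: dict[str, float] = Field(
        default_factory=lambda: {
            "age_years": 0.0,
            "bc_duration_months": 0.0076,
            "covid_season": 0.0,
            "renal_impairment": -0.205,
            "hepatic_impairment": 0.125,
            "lymph_node_metastasis": 1.075,
            "diabetes": -0.107,
            "cci_score": 0.158,
            "prior_bc_surgery": -1.256,
            "prior_non_bc_surgery": 0.430,
            "prior_radiotherapy": 1.411,
            "prior_anticancer": 0.509,
            "steroid_use": -0.643,
        }
    )
    hazard_log_coefficients: dict[str, float] = Field(
        default_factory=lambda: {
            "age_years": 0.01,
            "lymph_node_metastasis": 0.5,
            "diabetes": 0.3,
            "cci_score": 0.05,
            "prior_radiotherapy": 0.6,
            "steroid_use": 0.5,
        }
    )
    baseline_infection_rate: float = 0.35  # events per person-year in controls
    true_rate_ratio: float = 2.0
    covid_fraction_of_infections: float = 0.15
    hospital_los_mean: float = 8.0
    abx_course_mean_days: float = 7.5  # duration = 2 + Poisson(mean - 2)
    phenotype_emission: PhenotypeEmission = Field(default_factory=PhenotypeEmission)
    background: BackgroundRates = Field(default_factory=BackgroundRates)
    censoring_triggers: CensoringTriggers = Field(default_factory=CensoringTriggers)
    regimen: RegimenDuration = Field(default_factory=RegimenDuration)
    patient_mix: PatientMix = Field(default_factory=PatientMix)

    @classmethod
    def noisy(cls, **overrides) -> "SimulationParameters":
        """Preset with imperfect phenotype emission and background noise.

        Degrades the claims signal the way real extracts do: some infection
        episodes miss their hospitalization, primary-reason flag, test or
        antibacterial records, and unrelated hospitalizations, tests and
        antibacterial courses appear throughout.
        """
        base = dict(
            phenotype_emission=PhenotypeEmission(
                p_hospitalization=0.7,
                p_primary_diagnosis=0.7,
                p_immunological_test=0.8,
                p_iv_antibacterial=0.85,
            ),
            background=BackgroundRates(
                hospitalization=0.8,
                immunological_test=2.0,
                antibacterial_course=0.3,
                noninfection_diagnosis=3.0,
            ),
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """Latent per-patient truth emitted alongside the claims tables."""

    patients: pd.DataFrame  # one row per patient, covariates + latent fields
    true_rate_ratio: float

    def write(self, path) -> None:
        out = self.patients.copy()
        for col in out.columns:
            if np.issubdtype(out[col].dtype, np.datetime64):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


class _Streams:
    """Named independent RNG streams derived from the master seed."""

    _NAMES = (
        "mix", "dates", "covariates", "treatment", "regimen",
        "events", "emission", "records", "background", "visits",
    )

    def __init__(self, seed: int):
        children = np.random.SeedSequence(seed).spawn(len(self._NAMES))
        for name, child in zip(self._NAMES, children):
            setattr(self, name, np.random.default_rng(child))


def _draw_core(params: SimulationParameters, n: int, streams: _Streams):
    """Draw the latent patient core: mix, index dates, covariates, treatment.

    Returns a dict of aligned arrays.  Treatment probabilities are computed
    from the *final* covariates (after lookback truncation), so the fitted
    propensity model downstream is correctly specified.
    """
    mix, cov = params.patient_mix, params.covariates
    rng_mix, rng_dates, rng_cov, rng_trt = (
        streams.mix, streams.dates, streams.covariates, streams.treatment)

    u = rng_mix.random(n)
    patient_type = np.where(
        u < mix.p_no_study_drug, "no_study_drug",
        np.where(u < mix.p_no_study_drug + mix.p_atezo1200_only, "atezo1200_only", "regular"),
    )
    regular = patient_type == "regular"

    # index dates: pre/post COVID-season split inside the eligibility window
    w_lo, w_hi = (_day(d) for d in params.eligibility_window)
    season = _day(params.covid_season_start)
    covid = rng_dates.random(n) < cov.covid_season_fraction
    index_day = np.where(
        covid,
        rng_dates.integers(season, w_hi + 1, size=n),
        rng_dates.integers(w_lo, season, size=n),
    )

    # lookback / first record
    short = rng_mix.random(n) < mix.p_short_lookback
    lookback = np.where(
        short, rng_dates.integers(1, 90, size=n), rng_dates.integers(120, 2801, size=n)
    )
    first_day = index_day - lookback
    period_lo = _day(params.data_period[0])
    first_day = np.maximum(first_day, period_lo)
    lookback = index_day - first_day

    idx_month = index_day.astype("datetime64[D]").astype("datetime64[M]")
    fr_month = first_day.astype("datetime64[D]").astype("datetime64[M]")
    month_diff = (idx_month - fr_month).astype(int)

    age = np.clip(np.rint(rng_cov.normal(cov.age_mean, cov.age_sd, n)), 18, 95).astype(int)
    dur_raw = np.clip(np.rint(rng_cov.normal(cov.bc_duration_mean, cov.bc_duration_sd, n)), 0, None)
    bc_duration = np.minimum(dur_raw.astype(int), month_diff)
    cci = np.clip(np.rint(rng_cov.normal(cov.cci_mean, cov.cci_sd, n)), 0, 16).astype(int)
    binaries = {
        "renal_impairment": rng_cov.random(n) < cov.p_renal,
        "hepatic_impairment": rng_cov.random(n) < cov.p_hepatic,
        "lymph_node_metastasis": rng_cov.random(n) < cov.p_lymph_node,
        "diabetes": rng_cov.random(n) < cov.p_diabetes,
        "prior_bc_surgery": rng_cov.random(n) < cov.p_prior_bc_surgery,
        "prior_non_bc_surgery": rng_cov.random(n) < cov.p_prior_non_bc_surgery,
        "prior_radiotherapy": rng_cov.random(n) < cov.p_prior_radiotherapy,
        "prior_anticancer": rng_cov.random(n) < cov.p_prior_anticancer,
        "steroid_use": rng_cov.random(n) < cov.p_steroid,
    }
    # diagnosis-month-based covariates need a month strictly before the index
    # month; patients whose record starts in the index month cannot carry them
    no_prior_month = month_diff < 1
    for key in ("renal_impairment", "hepatic_impairment", "lymph_node_metastasis", "diabetes"):
        binaries[key] &= ~no_prior_month
    cci = np.where(no_prior_month, 0, cci)

    female = rng_cov.random(n) < cov.female_fraction

    covariates = {
        "age_years": age.astype(float),
        "bc_duration_months": bc_duration.astype(float),
        "covid_season": covid.astype(float),
        "cci_score": cci.astype(float),
    }
    covariates.update({k: v.astype(float) for k, v in binaries.items()})

    eta = np.zeros(n)
    for name, beta in params.treatment_logit_coefficients.items():
        x = covariates[name] - _CENTERS.get(name, 0.0)
        eta += beta * x

    # solve the intercept so the expected treated fraction among regular
    # candidates hits the target
    target = params.treated_fraction_target
    eta_reg = eta[regular] if regular.any() else eta
    if len(eta_reg):
        c0 = brentq(lambda c: expit(c + eta_reg).mean() - target, -20, 20)
    else:
        c0 = 0.0
    p_treat = expit(c0 + eta)
    treated = (rng_trt.random(n) < p_treat) & regular

    # log hazard (per person-year)
    log_h = np.log(params.baseline_infection_rate) * np.ones(n)
    for name, beta in params.hazard_log_coefficients.items():
        log_h += beta * (covariates[name] - _CENTERS.get(name, 0.0))
    log_h += np.log(params.true_rate_ratio) * treated
    hazard = np.exp(log_h)

    return dict(
        patient_type=patient_type, regular=regular, index_day=index_day,
        first_day=first_day, lookback=lookback, month_diff=month_diff,
        covariates=covariates, female=female, p_treat=p_treat, treated=treated,
        hazard=hazard, idx_month=idx_month,
    )


def _month_str(months: np.ndarray) -> np.ndarray:
    return np.datetime_as_string(months.astype("datetime64[M]"), unit="M")


def _cci_decompose(scores: np.ndarray) -> tuple[np.ndarray, ...]:
    """Counts of weight-6/3/2/1 categories reproducing each target score."""
    s = scores.astype(int)
    n6 = np.minimum(s // 6, 2)
    r = s - 6 * n6
    n3 = np.minimum(r // 3, 1)
    r = r - 3 * n3
    n2 = np.minimum(r // 2, 4)
    n1 = r - 2 * n2
    return n6, n3, n2, n1


def _spread(starts: np.ndarray, lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand (start, length) runs into (owner_index, offset) arrays."""
    lengths = lengths.astype(int)
    owners = np.repeat(np.arange(len(lengths)), lengths)
    offsets = np.arange(lengths.sum()) - np.repeat(np.cumsum(lengths) - lengths, lengths)
    return owners, offsets


_INFECTION_CODES = np.array(["A41.9", "B99.0", "J18.9", "N39.0"])
_COVID_CODE = "U07.1"
_ABX_CODES = np.array(["ABX01", "ABX02", "ABX03", "ABX04", "ABX05"])


def generate_claims_database(
    params: SimulationParameters,
) -> tuple[ClaimsDatabase, GroundTruth]:
    """Generate a synthetic :class:`ClaimsDatabase` plus its ground truth.

    Deterministic given ``params.seed``; ``n_patients=0`` yields valid empty
    tables.
    """
    n = params.n_patients
    streams = _Streams(params.seed)
    period = tuple(pd.Timestamp(d) for d in params.data_period)
    period_hi = _day(params.data_period[1])

    if n == 0:
        from .claims import empty_database

        db = empty_database(params.data_period)
        gt = GroundTruth(pd.DataFrame(), params.true_rate_ratio)
        return db, gt

    core = _draw_core(params, n, streams)
    mix = params.patient_mix
    pid = np.array([f"P{i:06d}" for i in range(n)])
    index_day = core["index_day"]
    first_day = core["first_day"]
    lookback = core["lookback"]
    regular = core["regular"]
    treated = core["treated"]
    covs = core["covariates"]
    rng_rec, rng_ev, rng_em = streams.records, streams.events, streams.emission
    rng_reg, rng_bg, rng_vis = streams.regimen, streams.background, streams.visits

    diag_parts, drug_parts, hosp_parts, lab_parts, proc_parts = [], [], [], [], []
    hosp_counter = [0]

    def new_hosp_ids(k: int) -> np.ndarray:
        ids = np.array([f"H{hosp_counter[0] + i:07d}" for i in range(k)])
        hosp_counter[0] += k
        return ids

    def add_diag(pids, months, codes, suspected=None, primary=None, linked=None):
        k = len(pids)
        if k == 0:
            return
        diag_parts.append(pd.DataFrame({
            "patient_id": pids,
            "code": codes if not np.isscalar(codes) else np.full(k, codes),
            "diagnosis_month": _month_str(months),
            "suspected": suspected if suspected is not None else np.zeros(k, bool),
            "primary_for_hospitalization": primary if primary is not None else np.zeros(k, bool),
            "linked_hospitalization_id": linked if linked is not None else np.full(k, None),
        }))

    def add_drug(pids, days, codes, route, dose, setting):
        k = len(pids)
        if k == 0:
            return
        drug_parts.append(pd.DataFrame({
            "patient_id": pids,
            "drug_code": codes if not np.isscalar(codes) else np.full(k, codes),
            "administration_date": _dates(np.minimum(days, period_hi)),
            "route": route if not np.isscalar(route) else np.full(k, route),
            "dose_mg": dose if not np.isscalar(dose) else np.full(k, float(dose)),
            "setting": setting if not np.isscalar(setting) else np.full(k, setting),
        }))

    def add_hosp(ids, pids, adm, dis):
        if len(ids) == 0:
            return
        hosp_parts.append(pd.DataFrame({
            "hospitalization_id": ids,
            "patient_id": pids,
            "admission_date": _dates(np.minimum(adm, period_hi)),
            "discharge_date": _dates(np.minimum(dis, period_hi)),
        }))

    def add_lab(pids, days, category="immunological_infection"):
        if len(pids) == 0:
            return
        lab_parts.append(pd.DataFrame({
            "patient_id": pids,
            "test_code": np.full(len(pids), "IMT01"),
            "test_date": _dates(np.minimum(days, period_hi)),
            "category": np.full(len(pids), category),
        }))

    def add_proc(pids, days, category, code):
        if len(pids) == 0:
            return
        proc_parts.append(pd.DataFrame({
            "patient_id": pids,
            "procedure_code": np.full(len(pids), code),
            "procedure_date": _dates(np.minimum(days, period_hi)),
            "category": np.full(len(pids), category),
        }))

    # ---- baseline (pre-index) records -----------------------------------
    idx_month = core["idx_month"]
    month_diff = core["month_diff"]
    bc_dur = covs["bc_duration_months"].astype(int)

    # breast-cancer diagnoses: earliest (index month − duration) and index month
    add_diag(pid, idx_month - bc_dur.astype("timedelta64[M]"), "C50.1")
    add_diag(pid, idx_month, "C50.1")

    # HER2-positive subpopulation
    her2 = (rng_rec.random(n) < mix.p_her2) & regular
    back = np.minimum(bc_dur, rng_rec.integers(0, 25, n))
    add_diag(pid[her2], (idx_month - back.astype("timedelta64[M]"))[her2], "C50H.0")

    # covariate diagnoses (strictly before the index month)
    cov_codes = {
        "renal_impairment": "N18.3",
        "hepatic_impairment": "K72.9",
        "lymph_node_metastasis": "C77.9",
        "diabetes": "E11.9",
    }
    for name, code in cov_codes.items():
        flag = covs[name].astype(bool)
        back = 1 + rng_rec.integers(0, np.maximum(np.minimum(month_diff, 36), 1), n)
        add_diag(pid[flag], (idx_month - back.astype("timedelta64[M]"))[flag], code)

    # comorbidity-index diagnoses decomposed into weighted categories
    cci = covs["cci_score"].astype(int)
    n6, n3, n2, n1 = _cci_decompose(cci)
    cm_groups = [(n6, ["CM16.0", "CM17.0"]), (n3, ["CM15.0"]),
                 (n2, ["CM11.0", "CM12.0", "CM13.0", "CM14.0"]),
                 (n1, [f"CM{i:02d}.0" for i in range(1, 11)])]
    for counts, code_pool in cm_groups:
        owners, offs = _spread(np.zeros(n, int), counts)
        if len(owners):
            back = 1 + rng_rec.integers(
                0, np.maximum(np.minimum(month_diff, 60), 1)[owners])
            add_diag(pid[owners], idx_month[owners] - back.astype("timedelta64[M]"),
                     np.array(code_pool)[offs % len(code_pool)])

    # pathological-diagnosis procedure (present for most patients)
    short = lookback <= 89
    has_path = np.where(
        short,
        rng_rec.random(n) < mix.p_short_lookback_with_pathology,
        rng_rec.random(n) < mix.p_pathological_dx,
    )
    path_day = first_day + rng_rec.integers(0, 30, n)
    path_day = np.minimum(path_day, index_day - 1)
    add_proc(pid[has_path], path_day[has_path], "pathological_diagnosis", "PRC-PATH")

    # prior procedures and drug histories, uniform in [first_record, index-1]
    def lookback_day():
        return first_day + (rng_rec.random(n) * np.maximum(lookback, 1)).astype(int)

    for name, cat, code in [
        ("prior_bc_surgery", "breast_cancer_surgery", "PRC-BCS"),
        ("prior_non_bc_surgery", "other_surgery", "PRC-OTH"),
        ("prior_radiotherapy", "radiotherapy", "PRC-RT"),
    ]:
        flag = covs[name].astype(bool)
        add_proc(pid[flag], lookback_day()[flag], cat, code)

    anti = covs["prior_anticancer"].astype(bool)
    add_drug(pid[anti], lookback_day()[anti], "HANC1", "intravenous", 100.0, "outpatient")

    ster = covs["steroid_use"].astype(bool)
    ster_lo = np.maximum(first_day, index_day - 90)
    ster_day = ster_lo + (rng_rec.random(n) * np.maximum(index_day - ster_lo, 1)).astype(int)
    add_drug(pid[ster], ster_day[ster], "STER1", "oral", 5.0, "outpatient")

    adj = (rng_rec.random(n) < mix.p_adjuvant_chemo) & regular
    add_drug(pid[adj], lookback_day()[adj], "ADJC1", "intravenous", 100.0, "outpatient")
    oreg = (rng_rec.random(n) < mix.p_other_regimen) & regular
    add_drug(pid[oreg], lookback_day()[oreg], "OREG1", "intravenous", 100.0, "outpatient")

    prior_sd = (rng_rec.random(n) < mix.p_prior_study_drug) & regular & (lookback > 250)
    psd_day = np.maximum(first_day, index_day - rng_rec.integers(200, 601, n))
    add_drug(pid[prior_sd], psd_day[prior_sd], "ATEZ", "intravenous", 1200.0, "outpatient")

    # ---- study-drug regimen ---------------------------------------------
    weeks = np.minimum(
        rng_reg.geometric(1.0 / params.regimen.mean_weeks, n), params.regimen.max_weeks)
    last_visit_eq_index = (rng_vis.random(n) < mix.p_index_equals_last_visit) & regular
    weeks = np.where(last_visit_eq_index, 1, weeks)

    candidate = regular | (core["patient_type"] == "atezo1200_only")
    # nab-paclitaxel weekly for regular patients
    owners, offs = _spread(np.zeros(n, int), np.where(regular, weeks, 0))
    add_drug(pid[owners], index_day[owners] + 7 * offs, "NABP", "intravenous", 260.0,
             "outpatient")
    # atezolizumab 840 mg q2w for the exposure arm
    n_atez = np.where(treated, 1 + (7 * (weeks - 1)) // 14, 0)
    owners, offs = _spread(np.zeros(n, int), n_atez)
    add_drug(pid[owners], index_day[owners] + 14 * offs, "ATEZ", "intravenous", 840.0,
             "outpatient")
    # atezolizumab-1200-only patients (never candidates)
    a12 = core["patient_type"] == "atezo1200_only"
    add_drug(pid[a12], index_day[a12], "ATEZ", "intravenous", 1200.0, "outpatient")

    # post-index censoring triggers
    ct = params.censoring_triggers
    trig_ok = regular & ~last_visit_eq_index

    def trig_day():
        return index_day + rng_reg.integers(ct.trigger_day_min, ct.trigger_day_max + 1, n)

    t1200 = (rng_reg.random(n) < ct.p_atezolizumab_1200) & trig_ok
    add_drug(pid[t1200], trig_day()[t1200], "ATEZ", "intravenous", 1200.0, "outpatient")
    toanc = (rng_reg.random(n) < ct.p_other_anticancer) & trig_ok
    add_drug(pid[toanc], trig_day()[toanc], "OANC1", "intravenous", 150.0, "outpatient")
    tswitch = (rng_reg.random(n) < ct.p_control_switch) & trig_ok & regular & ~treated
    switch_day = index_day + rng_reg.integers(40, 181, n)
    add_drug(pid[tswitch], switch_day[tswitch], "ATEZ", "intravenous", 840.0, "outpatient")

    # ---- severe-infection events ----------------------------------------
    em = params.phenotype_emission
    t_years = rng_ev.exponential(1.0 / core["hazard"], n)
    t_days = np.maximum(np.ceil(t_years * 365.25).astype(int), 1)
    has_event = regular & ~last_visit_eq_index & (t_days <= 210)

    ev = np.flatnonzero(has_event)
    k = len(ev)
    adm = index_day[ev] + t_days[ev]
    los = 1 + rng_ev.poisson(params.hospital_los_mean - 1, k)
    dis = adm + los
    e_hosp = rng_em.random(k) < em.p_hospitalization
    e_prim = (rng_em.random(k) < em.p_primary_diagnosis) & e_hosp
    e_test = rng_em.random(k) < em.p_immunological_test
    e_abx = rng_em.random(k) < em.p_iv_antibacterial

    covid_ev = (rng_ev.random(k) < params.covid_fraction_of_infections) & (
        adm >= _day(params.covid_season_start))
    codes = np.where(covid_ev, _COVID_CODE,
                     _INFECTION_CODES[rng_ev.integers(0, len(_INFECTION_CODES), k)])

    hosp_ids = new_hosp_ids(int(e_hosp.sum()))
    all_hosp_ids = np.full(k, None, dtype=object)
    all_hosp_ids[e_hosp] = hosp_ids
    add_hosp(hosp_ids, pid[ev][e_hosp], adm[e_hosp], dis[e_hosp])
    adm_month = adm.astype("datetime64[D]").astype("datetime64[M]")
    add_diag(pid[ev], adm_month, codes, primary=e_prim,
             linked=np.where(e_prim, all_hosp_ids, None))
    add_lab(pid[ev][e_test], (adm - rng_ev.integers(0, 15, k))[e_test])

    abx_dur = 2 + rng_ev.poisson(params.abx_course_mean_days - 2.0, k)
    owners, offs = _spread(np.zeros(k, int), np.where(e_abx, abx_dur, 0))
    day = adm[owners] + offs
    inpat = e_hosp[owners] & (day <= dis[owners])
    add_drug(pid[ev][owners], day,
             _ABX_CODES[rng_ev.integers(0, len(_ABX_CODES), len(owners))],
             "intravenous", 500.0, np.where(inpat, "inpatient", "outpatient"))

    # pre-index severe infection bundle (exclusion screen)
    pre = (rng_ev.random(n) < mix.p_preindex_infection) & regular & (lookback > 31)
    pv = np.flatnonzero(pre)
    kp = len(pv)
    if kp:
        adm_p = index_day[pv] - rng_ev.integers(1, 31, kp)
        dis_p = adm_p + 1 + rng_ev.poisson(5, kp)
        ids_p = new_hosp_ids(kp)
        add_hosp(ids_p, pid[pv], adm_p, dis_p)
        add_diag(pid[pv], adm_p.astype("datetime64[D]").astype("datetime64[M]"),
                 _INFECTION_CODES[rng_ev.integers(0, len(_INFECTION_CODES), kp)],
                 primary=np.ones(kp, bool), linked=ids_p)
        add_lab(pid[pv], adm_p)

    # ---- background noise -----------------------------------------------
    bg = params.background
    bg_lo = np.maximum(first_day, index_day - 365)
    bg_hi = np.where(last_visit_eq_index, index_day, index_day + 210)
    bg_years = np.maximum(bg_hi - bg_lo, 0) / 365.25

    def bg_days(rate):
        counts = rng_bg.poisson(rate * bg_years)
        owners, _ = _spread(np.zeros(n, int), counts)
        days = bg_lo[owners] + (
            rng_bg.random(len(owners)) * np.maximum(bg_hi - bg_lo, 1)[owners]).astype(int)
        return owners, days

    if bg.hospitalization > 0:
        owners, days = bg_days(bg.hospitalization)
        kb = len(owners)
        dis_b = days + 1 + rng_bg.poisson(4, kb)
        ids_b = new_hosp_ids(kb)
        add_hosp(ids_b, pid[owners], days, dis_b)
        # primary reason: non-infection code, or a *suspected* infection
        suspected_inf = rng_bg.random(kb) < 0.3
        add_diag(pid[owners], days.astype("datetime64[D]").astype("datetime64[M]"),
                 np.where(suspected_inf,
                          _INFECTION_CODES[rng_bg.integers(0, len(_INFECTION_CODES), kb)],
                          "Z51.1"),
                 suspected=suspected_inf, primary=np.ones(kb, bool), linked=ids_b)
    if bg.immunological_test > 0:
        owners, days = bg_days(bg.immunological_test)
        add_lab(pid[owners], days)
    if bg.antibacterial_course > 0:
        owners, days = bg_days(bg.antibacterial_course)
        dur = 2 + rng_bg.poisson(1.0, len(owners))
        o2, offs = _spread(np.zeros(len(owners), int), dur)
        add_drug(pid[owners][o2], days[o2] + offs,
                 _ABX_CODES[rng_bg.integers(0, len(_ABX_CODES), len(o2))],
                 "intravenous", 500.0, "outpatient")
    if bg.noninfection_diagnosis > 0:
        owners, days = bg_days(bg.noninfection_diagnosis)
        add_diag(pid[owners], days.astype("datetime64[D]").astype("datetime64[M]"), "Z00.0")

    # ---- assemble tables -------------------------------------------------
    def build(parts, columns, sort_keys):
        if parts:
            df = pd.concat(parts, ignore_index=True)[columns]
        else:
            df = pd.DataFrame({c: pd.Series(dtype=object) for c in columns})
        return df.sort_values(sort_keys, kind="stable").reset_index(drop=True)

    diagnoses = build(diag_parts,
                      ["patient_id", "code", "diagnosis_month", "suspected",
                       "primary_for_hospitalization", "linked_hospitalization_id"],
                      ["patient_id", "diagnosis_month", "code"])
    diagnoses["diagnosis_month"] = pd.PeriodIndex(diagnoses["diagnosis_month"], freq="M")
    diagnoses["suspected"] = diagnoses["suspected"].astype(bool)
    diagnoses["primary_for_hospitalization"] = (
        diagnoses["primary_for_hospitalization"].astype(bool))
    drugs = build(drug_parts,
                  ["patient_id", "drug_code", "administration_date", "route", "dose_mg",
                   "setting"], ["patient_id", "administration_date", "drug_code"])
    hosps = build(hosp_parts,
                  ["hospitalization_id", "patient_id", "admission_date", "discharge_date"],
                  ["patient_id", "admission_date", "hospitalization_id"])
    labs = build(lab_parts, ["patient_id", "test_code", "test_date", "category"],
                 ["patient_id", "test_date"])
    procs = build(proc_parts,
                  ["patient_id", "procedure_code", "procedure_date", "category"],
                  ["patient_id", "procedure_date", "category"])

    # last visit: latest record date plus a small gap (or exactly the index)
    max_day = pd.Series(first_day.copy(), index=pid)
    for df, col in [(drugs, "administration_date"), (hosps, "discharge_date"),
                    (labs, "test_date"), (procs, "procedure_date")]:
        if len(df):
            m = df.groupby("patient_id")[col].max()
            max_day.loc[m.index] = np.maximum(
                max_day.loc[m.index].to_numpy(),
                (m - pd.Timestamp(_EPOCH)).dt.days.to_numpy())
    last_day = np.minimum(max_day.to_numpy() + rng_vis.integers(10, 91, n), period_hi)
    last_day = np.where(last_visit_eq_index, index_day, last_day)
    last_day = np.maximum(last_day, index_day)

    patients = pd.DataFrame({
        "patient_id": pid,
        "sex": np.where(core["female"], "female", "male"),
        "birth_year": (index_day.astype("datetime64[D]").astype("datetime64[Y]")
                       .astype(int) + 1970) - covs["age_years"].astype(int),
        "first_record_date": _dates(first_day),
        "last_visit_date": _dates(last_day),
    })

    db = ClaimsDatabase(
        patients=patients, diagnoses=diagnoses, drugs=drugs, hospitalizations=hosps,
        labs=labs, procedures=procs, data_period=period)
    db.validate()

    gt = pd.DataFrame({"patient_id": pid, "patient_type": core["patient_type"]})
    for name in COVARIATE_NAMES:
        gt[name] = covs[name]
    gt["female"] = core["female"]
    gt["p_treat"] = core["p_treat"]
    gt["treated"] = treated
    gt["index_date"] = _dates(index_day)
    gt["first_record_date"] = _dates(first_day)
    gt["regimen_weeks"] = weeks
    gt["event_time_days"] = t_days
    gt["has_event_210"] = has_event
    gt["her2"] = her2
    gt["adjuvant_chemo"] = adj
    gt["other_regimen_history"] = oreg
    gt["prior_study_drug"] = prior_sd
    gt["preindex_infection"] = pre
    gt["index_equals_last_visit"] = last_visit_eq_index
    gt["short_lookback"] = short
    gt["has_pathological_dx"] = has_path
    gt["true_rate_ratio"] = params.true_rate_ratio

    return db, GroundTruth(gt, params.true_rate_ratio)


@dataclass
class ExpectedSummaries:
    """Closed-form/Monte-Carlo expectations under the generative model."""

    treated_fraction: float
    rate_exposure: float
    rate_control: float
    irr_unadjusted: float
    irr_smrw_adjusted: float


def expected_summaries(
    params: SimulationParameters,
    n_mc: int = 200_000,
    mc_seed: int = 987654321,
    grace_days: int = 28,
) -> ExpectedSummaries:
    """Analytic expectations of the generative model, marginalised over
    covariates by large-sample Monte Carlo with its own fixed seed.

    Per patient the censoring time is ``min(210, 7(W−1) + grace_days)``
    (regimen end with the analysis grace period) and the exponential
    identities ``E[events] = 1 − e^{−λC}``, ``E[time] = E[events]/λ`` give
    exact conditional expectations; only the covariate mixture is sampled.
    The SMR-weighted control expectation reweights controls by the
    propensity odds, i.e. by ``p(x)`` overall.
    """
    streams = _Streams(mc_seed)
    core = _draw_core(params, n_mc, streams)
    p = core["p_treat"]
    h0 = core["hazard"] / np.where(core["treated"], params.true_rate_ratio, 1.0)
    h1 = h0 * params.true_rate_ratio
    weeks = np.minimum(
        streams.regimen.geometric(1.0 / params.regimen.mean_weeks, n_mc),
        params.regimen.max_weeks)
    c_years = np.minimum(210, 7 * (weeks - 1) + grace_days) / 365.25

    def rate(h, w):
        ev = 1.0 - np.exp(-h * c_years)
        return float((w * ev).sum() / (w * ev / h).sum())

    r_e = rate(h1, p)
    r_c = rate(h0, 1.0 - p)
    r_c_smrw = rate(h0, (1.0 - p) * p / (1.0 - p))  # = p
    return ExpectedSummaries(
        treated_fraction=float(p.mean()),
        rate_exposure=r_e,
        rate_control=r_c,
        irr_unadjusted=r_e / r_c,
        irr_smrw_adjusted=r_e / r_c_smrw,
    )
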