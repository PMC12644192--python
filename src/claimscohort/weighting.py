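"""Baseline covariates, propensity model, SMR weights, balance diagnostics.

The 13 baseline covariates are derived from pre-index claims records:
age at index, breast-cancer duration in months, COVID-season indicator,
four diagnosis-history flags, a weighted comorbidity-index score, three
procedure-history flags, anticancer-drug history, and recent steroid use.
A maximum-likelihood logistic regression of treatment on the main
effects gives the propensity score PS; standardized mortality/morbidity
ratio weighting (SMRW) assigns weight 1 to every exposure patient and
the propensity odds PS/(1−PS) to every control, targeting the treated
population (ATT).  Overlap trimming restricts each group to the other
group's observed PS range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .claims import ClaimsDatabase, CodeLists, match_codes
from .simulate import COVARIATE_NAMES

__all__ = [
    "CONTINUOUS_COVARIATES",
    "PropensityResult",
    "WeightAssignment",
    "SeparationError",
    "balance_table",
    "derive_covariates",
    "fit_propensity_model",
    "smr_weights",
    "standardized_difference",
    "trim_by_overlap",
    "weighted_mean_sd",
]

CONTINUOUS_COVARIATES = ("age_years", "bc_duration_months", "cci_score")


class SeparationError(ValueError):
    """Complete separation in the propensity model."""


def derive_covariates(
    cohort: pd.DataFrame,
    db: ClaimsDatabase,
    codes: CodeLists,
    covid_season_start: str | pd.Timestamp = "2020-04-01",
    steroid_window_days: int = 90,
) -> pd.DataFrame:
    """Derive the 13 baseline covariates (plus ``female``) per patient.

    Binary diagnosis histories count confirmed diagnoses in months strictly
    before the index month; procedure and drug histories count records
    strictly before the index date; steroid use is restricted to the
    ``steroid_window_days`` days before the index.  The comorbidity score
    sums the configured weights over distinct comorbidity categories seen
    before the index month.
    """
    c = cohort.set_index("patient_id")
    idx = c["index_date"]
    idx_month = pd.PeriodIndex(idx, freq="M")
    idx_month = pd.Series(idx_month, index=c.index)
    out = pd.DataFrame(index=c.index)

    pat = db.patients.set_index("patient_id")
    birth = c.index.map(pat["birth_year"])
    if pd.isna(birth).any():
        missing = list(c.index[pd.isna(birth)])[:5]
        raise ValueError(f"missing birth_year for patient(s) {missing}")
    out["age_years"] = (idx.dt.year - pd.Series(birth, index=c.index)).astype(float)
    out["female"] = pd.Series(c.index.map(pat["sex"]), index=c.index) == "female"

    dx = db.diagnoses[db.diagnoses["patient_id"].isin(set(c.index))]
    confirmed = dx[~dx["suspected"]]

    bc = confirmed[match_codes(confirmed["code"], codes.breast_cancer)]
    earliest = bc.groupby("patient_id")["diagnosis_month"].min().reindex(c.index)
    dur = (idx_month - earliest).map(lambda d: d.n if pd.notna(d) else 0)
    out["bc_duration_months"] = dur.clip(lower=0).astype(float)

    out["covid_season"] = idx >= pd.Timestamp(covid_season_start)

    pre = confirmed.join(idx_month.rename("index_month"), on="patient_id")
    pre = pre[pre["diagnosis_month"] < pre["index_month"]]
    for name, code_list in codes.covariate_diagnosis.items():
        hits = pre[match_codes(pre["code"], code_list)]["patient_id"].unique()
        out[name] = out.index.isin(hits)
    for name in ("renal_impairment", "hepatic_impairment",
                 "lymph_node_metastasis", "diabetes"):
        if name not in out.columns:
            out[name] = False

    # comorbidity index: distinct categories, weights summed
    score = pd.Series(0.0, index=c.index)
    seen: dict[str, pd.Index] = {}
    for entry in codes.comorbidity_map:
        if entry.match == "prefix":
            hit = pre[pre["code"].astype(str).str.startswith(entry.pattern)]
        else:
            hit = pre[pre["code"] == entry.pattern]
        ids = pd.Index(hit["patient_id"].unique())
        prev = seen.get(entry.category, pd.Index([]))
        new = ids.difference(prev)
        score.loc[score.index.intersection(new)] += entry.weight
        seen[entry.category] = prev.union(ids)
    out["cci_score"] = score

    procs = db.procedures.join(idx.rename("index_date"), on="patient_id")
    procs = procs[procs["index_date"].notna()
                  & (procs["procedure_date"] < procs["index_date"])]
    for name, cat in [
        ("prior_bc_surgery", "breast_cancer_surgery"),
        ("prior_non_bc_surgery", "other_surgery"),
        ("prior_radiotherapy", "radiotherapy"),
    ]:
        out[name] = out.index.isin(procs.loc[procs["category"] == cat, "patient_id"])

    drugs = db.drugs.join(idx.rename("index_date"), on="patient_id")
    drugs = drugs[drugs["index_date"].notna()]
    hist = drugs[match_codes(drugs["drug_code"], codes.anticancer_history)
                 & (drugs["administration_date"] < drugs["index_date"])]
    out["prior_anticancer"] = out.index.isin(hist["patient_id"])

    ster = drugs[match_codes(drugs["drug_code"], codes.steroid)
                 & (drugs["administration_date"] < drugs["index_date"])
                 & (drugs["administration_date"]
                    >= drugs["index_date"] - pd.Timedelta(days=steroid_window_days))]
    out["steroid_use"] = out.index.isin(ster["patient_id"])

    for name in COVARIATE_NAMES:
        if out[name].dtype == bool:
            out[name] = out[name].astype(float)
    return out[COVARIATE_NAMES + ["female"]]


@dataclass
class PropensityResult:
    ps: pd.Series
    coefficients: pd.Series
    converged: bool
    llf: float
    dropped_covariates: list[str] = field(default_factory=list)


def fit_propensity_model(
    covariates: pd.DataFrame,
    treatment: pd.Series,
    columns: list[str] | None = None,
) -> PropensityResult:
    """Maximum-likelihood logistic regression of treatment on main effects.

    Constant covariates are dropped with a warning; complete separation
    raises :class:`SeparationError` naming the offending covariate(s).
    Deterministic given the data (Newton-Raphson, relative log-likelihood
    tolerance 1e-8, at most 100 iterations).
    """
    cols = list(columns) if columns is not None else [
        c for c in COVARIATE_NAMES if c in covariates.columns]
    X = covariates[cols].astype(float)
    y = treatment.reindex(X.index).astype(float)
    if y.nunique() < 2:
        raise ValueError("need at least one patient in each group")

    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant covariate(s): {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)

    # binary covariates with an empty treatment-by-level cell: one empty
    # cell is quasi-separation (the MLE diverges for that coefficient alone)
    # and the covariate is dropped with a warning; two empty cells mean the
    # covariate classifies treatment perfectly — fatal.
    for col in list(X.columns):
        if X[col].nunique() == 2:
            tab = pd.crosstab(X[col], y)
            n_zero = int((tab == 0).to_numpy().sum())
            if n_zero >= 2:
                raise SeparationError(
                    f"complete separation: covariate {col!r} perfectly "
                    "predicts treatment")
            if n_zero == 1:
                warnings.warn(
                    f"dropping quasi-separated covariate {col!r} "
                    "(empty treatment-by-level cell)", stacklevel=2)
                X = X.drop(columns=[col])
                dropped.append(col)

    try:
        model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
        res = model.fit(method="newton", tol=1e-8, maxiter=100, disp=0)
    except Exception as exc:  # statsmodels PerfectSeparation* or numerical
        culprits = _separating_covariates(X, y)
        raise SeparationError(
            "propensity model failed (possible complete separation); "
            f"suspect covariate(s): {culprits or 'unknown'}") from exc
    ps = pd.Series(np.asarray(res.predict()), index=X.index, name="ps")
    if ((ps <= 0) | (ps >= 1)).any():
        culprits = _separating_covariates(X, y)
        raise SeparationError(
            f"fitted propensity scores outside (0,1); suspect covariate(s): {culprits}")
    return PropensityResult(
        ps=ps, coefficients=res.params, converged=bool(res.mle_retvals["converged"]),
        llf=float(res.llf), dropped_covariates=dropped)


def _separating_covariates(X: pd.DataFrame, y: pd.Series) -> list[str]:
    out = []
    for col in X.columns:
        if X[col].nunique() == 2:
            tab = pd.crosstab(X[col], y)
            if (tab == 0).any().any():
                out.append(col)
    return out


@dataclass
class WeightAssignment:
    weights: pd.Series
    scheme: str  # "unadjusted" | "smrw"
    weighted_n: dict[str, float]


def smr_weights(
    ps: PropensityResult | pd.Series,
    treatment: pd.Series,
    eps: float = 1e-12,
) -> WeightAssignment:
    """SMR weights: 1 for exposure patients, PS/(1−PS) for controls."""
    scores = ps.ps if isinstance(ps, PropensityResult) else ps
    scores = scores.reindex(treatment.index)
    t = treatment.astype(bool)
    if (scores[~t] >= 1 - eps).any():
        raise ValueError("control propensity score at 1: SMR weight diverges")
    w = pd.Series(np.where(t, 1.0, scores / (1.0 - scores)),
                  index=treatment.index, name="weight")
    weighted_n = {
        "exposure": float(w[t].sum()),
        "control": float(w[~t].sum()),
    }
    return WeightAssignment(weights=w, scheme="smrw", weighted_n=weighted_n)


def unadjusted_weights(treatment: pd.Series) -> WeightAssignment:
    w = pd.Series(1.0, index=treatment.index, name="weight")
    t = treatment.astype(bool)
    return WeightAssignment(
        weights=w, scheme="unadjusted",
        weighted_n={"exposure": float(t.sum()), "control": float((~t).sum())})


def trim_by_overlap(
    ps: PropensityResult | pd.Series,
    treatment: pd.Series,
) -> pd.Series:
    """Overlap trimming: keep patients inside the other group's PS range.

    Boundaries inclusive.  Raises if either group empties.
    """
    scores = ps.ps if isinstance(ps, PropensityResult) else ps
    scores = scores.reindex(treatment.index)
    t = treatment.astype(bool)
    lo_e, hi_e = scores[t].min(), scores[t].max()
    lo_c, hi_c = scores[~t].min(), scores[~t].max()
    keep = pd.Series(
        np.where(t, (scores >= lo_c) & (scores <= hi_c),
                 (scores >= lo_e) & (scores <= hi_e)),
        index=treatment.index, name="retained")
    if not (keep & t).any() or not (keep & ~t).any():
        raise ValueError("a group is empty after overlap trimming")
    return keep


def weighted_mean_sd(x: pd.Series, w: pd.Series) -> tuple[float, float]:
    """Weighted mean and SD under the frequency-weight convention
    (variance denominator Σw − 1)."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    m = float((w * x).sum() / sw)
    if sw <= 1:
        return m, float("nan")
    var = float((w * (x - m) ** 2).sum() / (sw - 1))
    return m, np.sqrt(var)


def standardized_difference(
    summary1: tuple[float, float] | float,
    summary2: tuple[float, float] | float,
    kind: str = "continuous",
) -> float:
    """Standardized difference between two group summaries.

    ``continuous``: summaries are (mean, SD); d = (m1−m2)/√((s1²+s2²)/2).
    ``binary``: summaries are proportions; the SD is the Bernoulli SD.
    Sign is group1 − group2.  Zero pooled variance with a nonzero
    difference yields ±inf.
    """
    if kind == "continuous":
        m1, s1 = summary1
        m2, s2 = summary2
        pooled = (s1 ** 2 + s2 ** 2) / 2.0
    elif kind == "binary":
        p1, p2 = float(summary1), float(summary2)
        m1, m2 = p1, p2
        pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
    else:
        raise ValueError(f"unknown kind {kind!r}")
    diff = m1 - m2
    if pooled <= 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(pooled))


def balance_table(
    covariates: pd.DataFrame,
    treatment: pd.Series,
    weights: pd.Series | None = None,
    continuous: tuple[str, ...] = CONTINUOUS_COVARIATES,
    include: list[str] | None = None,
) -> pd.DataFrame:
    """Covariate balance before and after weighting.

    One row per covariate with unadjusted and adjusted group summaries
    (mean/SD for continuous covariates, proportion for binary ones),
    weighted group sizes, and standardized differences.  ``weights`` of
    ``None`` reports the adjusted columns as identical to the unadjusted.
    """
    t = treatment.astype(bool)
    if weights is None:
        weights = pd.Series(1.0, index=treatment.index)
    w1 = pd.Series(1.0, index=treatment.index)
    rows = []
    cols = include if include is not None else list(covariates.columns)
    for name in cols:
        x = covariates[name].astype(float)
        kind = "continuous" if name in continuous else "binary"
        row: dict[str, object] = {"covariate": name, "kind": kind}
        for tag, w in (("unadj", w1), ("adj", weights)):
            me, se = weighted_mean_sd(x[t], w[t])
            mc, sc = weighted_mean_sd(x[~t], w[~t])
            if kind == "continuous":
                d = standardized_difference((me, se), (mc, sc), "continuous")
            else:
                d = standardized_difference(me, mc, "binary")
            row.update({
                f"exposure_mean_{tag}": me, f"exposure_sd_{tag}": se,
                f"control_mean_{tag}": mc, f"control_sd_{tag}": sc,
                f"d_{tag}": d,
            })
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["weighted_n"] = {
        "exposure_unadj": float(t.sum()), "control_unadj": float((~t).sum()),
        "exposure_adj": float(weights[t].sum()), "control_adj": float(weights[~t].sum()),
    }
    return table
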