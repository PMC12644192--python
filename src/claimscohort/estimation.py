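"""Incidence rates, rate ratios, the sample-size planner, and Kaplan–Meier.

Rate CIs are Wald intervals on the natural scale (they may cross zero,
matching how person-time incidence is conventionally reported in this
design); rate-ratio CIs are Wald intervals on the log scale with
effective event counts (Σwe)²/(Σw²e) substituting for raw counts under
weighting.  z is fixed at 1.96 for α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "WeightedRateEstimate",
    "RateRatioEstimate",
    "PlanningInputs",
    "PlanningResult",
    "incidence_rate",
    "rate_from_person_time",
    "rate_ratio",
    "planning_expected_ci",
    "km_curve",
    "clinical_event_summary",
]


def _z(alpha: float) -> float:
    return 1.96 if alpha == 0.05 else float(norm.ppf(1 - alpha / 2))


@dataclass
class WeightedRateEstimate:
    group: str
    events: float  # Σ wᵢ eᵢ
    person_years: float
    rate: float  # per person-year
    ci_low: float
    ci_high: float
    var_events: float  # Σ wᵢ² eᵢ (equals events when unweighted)
    flagged: bool = False

    @property
    def effective_events(self) -> float:
        """(Σwe)²/(Σw²e): the Poisson-equivalent event count under weighting."""
        if self.var_events == 0:
            return 0.0
        return self.events ** 2 / self.var_events


def incidence_rate(
    events: float,
    person_years: float,
    var_events: float | None = None,
    group: str = "",
    alpha: float = 0.05,
) -> WeightedRateEstimate:
    """Person-time incidence rate with a natural-scale Wald CI.

    ``var_events`` is Σw²e for weighted counts (defaults to ``events``,
    the unweighted Poisson variance).  Zero person-time is undefined and
    flagged; zero events give the degenerate CI [0, 0], flagged.
    """
    if var_events is None:
        var_events = events
    if person_years <= 0:
        return WeightedRateEstimate(group, events, person_years,
                                    float("nan"), float("nan"), float("nan"),
                                    var_events, flagged=True)
    rate = events / person_years
    if events == 0:
        return WeightedRateEstimate(group, events, person_years, 0.0, 0.0, 0.0,
                                    var_events, flagged=True)
    se = np.sqrt(var_events) / person_years
    z = _z(alpha)
    return WeightedRateEstimate(group, events, person_years, rate,
                                rate - z * se, rate + z * se, var_events)


def rate_from_person_time(row: pd.Series, alpha: float = 0.05) -> WeightedRateEstimate:
    """Build a rate estimate from one row of ``person_time_by_group`` output."""
    return incidence_rate(
        events=row["event_count"], person_years=row["total_person_years"],
        var_events=row.get("event_count_w2", row["event_count"]),
        group=row["group"], alpha=alpha)


@dataclass
class RateRatioEstimate:
    irr: float
    ci_low: float
    ci_high: float
    flagged: bool = False


def rate_ratio(
    exposure: WeightedRateEstimate,
    control: WeightedRateEstimate,
    continuity: float = 0.5,
    alpha: float = 0.05,
) -> RateRatioEstimate:
    """Incidence rate ratio (exposure/control) with a log-scale Wald CI.

    Effective event counts replace raw counts under weighting.  When either
    count is zero, ``continuity`` is added to both effective counts (and the
    point estimate uses the corrected counts); two zero counts are
    undefined and flagged.
    """
    we, wc = exposure.events, control.events  # weighted event sums
    ee, ec = exposure.effective_events, control.effective_events
    flagged = False
    if we == 0 and wc == 0:
        return RateRatioEstimate(float("nan"), float("nan"), float("nan"), True)
    if we == 0 or wc == 0:
        we, wc = we + continuity, wc + continuity
        ee, ec = ee + continuity, ec + continuity
        flagged = True
    irr = (we / exposure.person_years) / (wc / control.person_years)
    z = _z(alpha)
    half = z * np.sqrt(1.0 / ee + 1.0 / ec)
    return RateRatioEstimate(
        irr=float(irr),
        ci_low=float(irr * np.exp(-half)),
        ci_high=float(irr * np.exp(half)),
        flagged=flagged,
    )


@dataclass
class PlanningInputs:
    """Inputs to the design-stage expected-CI calculation."""

    n_per_group: int
    control_rate: float  # events per person-year
    observation_weeks: float
    rate_ratio_assumed: float
    alpha: float = 0.05


@dataclass
class PlanningResult:
    expected_irr: float
    ci_low: float
    ci_high: float
    expected_events_exposure: float
    expected_events_control: float
    person_years_per_group: float


def planning_expected_ci(p: PlanningInputs) -> PlanningResult:
    """Expected IRR confidence interval for a planned study size.

    Person-time per group is n × weeks × 7/365.25 person-years; expected
    control events are rate × T, expected exposure events the assumed
    ratio times that; the CI is the log-scale Wald interval evaluated at
    the expected counts.
    """
    t = p.n_per_group * p.observation_weeks * 7.0 / 365.25
    ec = p.control_rate * t
    ee = p.rate_ratio_assumed * ec
    est_e = incidence_rate(ee, t, group="exposure", alpha=p.alpha)
    est_c = incidence_rate(ec, t, group="control", alpha=p.alpha)
    rr = rate_ratio(est_e, est_c, alpha=p.alpha)
    return PlanningResult(
        expected_irr=rr.irr, ci_low=rr.ci_low, ci_high=rr.ci_high,
        expected_events_exposure=ee, expected_events_control=ec,
        person_years_per_group=t)


def km_curve(
    time_days: pd.Series | np.ndarray,
    event: pd.Series | np.ndarray,
    weights: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Weighted product-limit (Kaplan–Meier) survival estimate.

    S(t) = Π_{t_j ≤ t} (1 − d_j/n_j) over distinct event times t_j, with
    d_j and n_j weighted sums of events and patients at risk.  Censoring
    happens after events at tied times (standard convention).  Returns a
    DataFrame of event times with ``n_risk``, ``n_events`` and
    ``survival``; S(0) = 1 is included as the first row.
    """
    t = np.asarray(time_days, dtype=float)
    e = np.asarray(event, dtype=bool)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    order = np.argsort(t, kind="stable")
    t, e, w = t[order], e[order], w[order]

    rows = [{"time": 0.0, "n_risk": float(w.sum()), "n_events": 0.0, "survival": 1.0}]
    surv = 1.0
    for tj in np.unique(t[e]):
        n_risk = float(w[t >= tj].sum())
        d = float(w[e & (t == tj)].sum())
        if n_risk > 0:
            surv *= 1.0 - d / n_risk
        rows.append({"time": float(tj), "n_risk": n_risk, "n_events": d,
                     "survival": surv})
    return pd.DataFrame(rows)


def clinical_event_summary(
    followups: pd.DataFrame,
    db,
    codes,
    weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-group clinical-event descriptives during observation.

    Hospitalization admissions inside [index, end_date] are summarized as
    weighted mean ± SD per patient; surgery, radiotherapy and steroid use
    as weighted percentages of patients with at least one record in the
    window.
    """
    from .claims import match_codes
    from .weighting import weighted_mean_sd

    f = followups.set_index("patient_id")
    if weights is None:
        w = pd.Series(1.0, index=f.index)
    else:
        w = weights.reindex(f.index).astype(float)

    def in_window(df, col):
        d = df.join(f[["index_date", "end_date"]], on="patient_id")
        d = d[d["index_date"].notna()]
        return d[(d[col] >= d["index_date"]) & (d[col] <= d["end_date"])]

    hosp_n = in_window(db.hospitalizations, "admission_date").groupby(
        "patient_id").size().reindex(f.index, fill_value=0).astype(float)

    procs = in_window(db.procedures, "procedure_date")
    surgery = procs[procs["category"].isin(["breast_cancer_surgery", "other_surgery"])]
    radio = procs[procs["category"] == "radiotherapy"]
    drugs = in_window(db.drugs, "administration_date")
    steroid = drugs[match_codes(drugs["drug_code"], codes.steroid)]

    rows = []
    for group, sub in f.groupby("group"):
        ids = sub.index
        wg = w.loc[ids]
        m, s = weighted_mean_sd(hosp_n.loc[ids], wg)
        row = {"group": group, "weighted_n": float(wg.sum()),
               "hospitalizations_mean": m, "hospitalizations_sd": s}
        for name, df in [("surgery", surgery), ("radiotherapy", radio),
                         ("steroid_use", steroid)]:
            flag = pd.Index(ids).isin(df["patient_id"].unique()).astype(float)
            row[f"{name}_pct"] = float(100.0 * (wg.to_numpy() * flag).sum() / wg.sum())
        rows.append(row)
    return pd.DataFrame(rows)
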