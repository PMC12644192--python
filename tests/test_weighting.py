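"""Covariate derivation, propensity fitting, SMR weights, balance."""

import numpy as np
import pandas as pd
import pytest

from claimscohort.claims import CodeList, ComorbidityEntry
from claimscohort.cohort import build_cohort
from claimscohort.weighting import (
    PropensityResult,
    SeparationError,
    balance_table,
    derive_covariates,
    fit_propensity_model,
    smr_weights,
    standardized_difference,
    trim_by_overlap,
    unadjusted_weights,
    weighted_mean_sd,
)

from _helpers import bc_dx, drug, make_db, patient


def _cohort(pid="P1", index="2021-04-15", group="exposure"):
    return pd.DataFrame({"patient_id": [pid], "index_date": [pd.Timestamp(index)],
                         "group": [group]})


def test_breast_cancer_duration_month_arithmetic(codes):
    db = make_db(
        patients=[patient("P1", birth=1961)],
        diagnoses=[bc_dx("P1", "2019-01"), bc_dx("P1", "2021-04")],
    )
    cov = derive_covariates(_cohort(index="2021-04-15"), db, codes)
    assert cov.loc["P1", "bc_duration_months"] == 27.0
    assert cov.loc["P1", "age_years"] == 60.0


def test_cci_sums_distinct_category_weights(codes):
    """Metastatic solid tumour (6) + uncomplicated diabetes (1) -> score 7,
    repeated codes in one category counted once."""
    custom = codes.model_copy(update={"comorbidity_map": [
        ComorbidityEntry(pattern="C78", category="metastatic_solid_tumour", weight=6),
        ComorbidityEntry(pattern="E11", category="diabetes_uncomplicated", weight=1),
    ]})
    db = make_db(
        patients=[patient("P1")],
        diagnoses=[bc_dx("P1", "2021-04"),
                   bc_dx("P1", "2020-01", code="C78.0"),
                   bc_dx("P1", "2020-05", code="C78.1"),
                   bc_dx("P1", "2020-06", code="E11.9")],
    )
    cov = derive_covariates(_cohort(index="2021-04-15"), db, custom)
    assert cov.loc["P1", "cci_score"] == 7.0


def test_covid_season_flag(codes):
    db = make_db(patients=[patient("P1")], diagnoses=[bc_dx("P1", "2020-06")])
    cov = derive_covariates(_cohort(index="2020-06-01"), db, codes,
                            covid_season_start="2020-04-01")
    assert cov.loc["P1", "covid_season"] == 1.0
    cov = derive_covariates(_cohort(index="2020-06-01"), db, codes,
                            covid_season_start="2020-07-01")
    assert cov.loc["P1", "covid_season"] == 0.0


def test_steroid_use_requires_recent_window(codes):
    db = make_db(
        patients=[patient("P1")],
        diagnoses=[bc_dx("P1", "2021-04")],
        drugs=[drug("P1", "STER1", "2020-06-01", 5)],  # > 90 d before index
    )
    cov = derive_covariates(_cohort(index="2021-04-15"), db, codes)
    assert cov.loc["P1", "steroid_use"] == 0.0
    db2 = make_db(
        patients=[patient("P1")],
        diagnoses=[bc_dx("P1", "2021-04")],
        drugs=[drug("P1", "STER1", "2021-03-01", 5)],
    )
    cov2 = derive_covariates(_cohort(index="2021-04-15"), db2, codes)
    assert cov2.loc["P1", "steroid_use"] == 1.0


def test_diagnosis_history_strictly_before_index_month(codes):
    db = make_db(
        patients=[patient("P1")],
        diagnoses=[bc_dx("P1", "2021-04"),
                   bc_dx("P1", "2021-04", code="E11.9")],  # same month: no history
    )
    cov = derive_covariates(_cohort(index="2021-04-15"), db, codes)
    assert cov.loc["P1", "diabetes"] == 0.0


def test_logistic_2x2_closed_form():
    """Saturated 2x2: slope = log OR = ln((30*30)/(10*10)) = ln 9."""
    x = pd.Series([1.0] * 30 + [0.0] * 10 + [1.0] * 10 + [0.0] * 30, name="x")
    y = pd.Series([True] * 40 + [False] * 40)
    x.index = y.index = range(80)
    res = fit_propensity_model(pd.DataFrame({"x": x}), y, columns=["x"])
    assert res.coefficients["x"] == pytest.approx(np.log(9.0), abs=1e-6)
    assert res.converged


def test_null_model_slopes_within_3se():
    rng = np.random.default_rng(12)
    n = 4000
    X = pd.DataFrame({
        "a": rng.normal(size=n),
        "b": (rng.random(n) < 0.4).astype(float),
        "c": rng.normal(2, 1, size=n),
    })
    y = pd.Series(rng.random(n) < 0.45)
    res = fit_propensity_model(X, y, columns=["a", "b", "c"])
    import statsmodels.api as sm

    fit = sm.Logit(y.astype(float), sm.add_constant(X)).fit(disp=0)
    for c in ("a", "b", "c"):
        assert abs(res.coefficients[c]) < 3 * fit.bse[c]
    assert res.ps.between(0, 1).all()
    assert res.ps.std() < 0.05  # concentrated near the marginal fraction


def test_duplicated_data_identical_coefficients():
    rng = np.random.default_rng(5)
    X = pd.DataFrame({"a": rng.normal(size=300), "b": rng.random(300) < 0.5})
    y = pd.Series(rng.random(300) < 1 / (1 + np.exp(-X["a"])))
    res1 = fit_propensity_model(X.astype(float), y, columns=["a", "b"])
    X2 = pd.concat([X, X], ignore_index=True).astype(float)
    y2 = pd.concat([y, y], ignore_index=True)
    res2 = fit_propensity_model(X2, y2, columns=["a", "b"])
    for c in ("a", "b"):
        assert res1.coefficients[c] == pytest.approx(res2.coefficients[c], abs=1e-6)


def test_constant_covariate_dropped_with_warning():
    rng = np.random.default_rng(6)
    X = pd.DataFrame({"a": rng.normal(size=200), "k": 1.0})
    y = pd.Series(rng.random(200) < 0.5)
    with pytest.warns(UserWarning, match="constant"):
        res = fit_propensity_model(X, y, columns=["a", "k"])
    assert res.dropped_covariates == ["k"]
    assert "k" not in res.coefficients


def test_complete_separation_names_covariate():
    X = pd.DataFrame({"sep": [1.0] * 50 + [0.0] * 50})
    y = pd.Series([True] * 50 + [False] * 50)
    with pytest.raises(SeparationError, match="sep"):
        fit_propensity_model(X, y, columns=["sep"])


def test_smr_weight_values():
    ps = pd.Series([0.3, 0.5, 0.8], index=["a", "b", "c"])
    treated = pd.Series([True, False, False], index=["a", "b", "c"])
    wa = smr_weights(ps, treated)
    assert wa.weights["a"] == 1.0
    assert wa.weights["b"] == pytest.approx(1.0)
    assert wa.weights["c"] == pytest.approx(4.0)
    assert wa.weighted_n["exposure"] == 1.0


def test_exposure_weighted_n_equals_unweighted(small_perfect_db, codes):
    db, _ = small_perfect_db
    cohort, _ = build_cohort(db, codes)
    cov = derive_covariates(cohort, db, codes)
    treated = cohort.set_index("patient_id")["group"].eq("exposure")
    wa = smr_weights(fit_propensity_model(cov, treated), treated)
    assert (wa.weights[treated] == 1.0).all()
    assert wa.weighted_n["exposure"] == float(treated.sum())


def test_control_ps_of_one_is_fatal():
    ps = pd.Series([0.5, 1.0], index=["a", "b"])
    treated = pd.Series([True, False], index=["a", "b"])
    with pytest.raises(ValueError, match="diverges"):
        smr_weights(ps, treated)


def test_trimming_rule_and_oracle(small_perfect_db, codes):
    # forced example
    ps = pd.Series([0.2, 0.85, 0.9, 0.1, 0.12, 0.8],
                   index=list("abcdef"))
    treated = pd.Series([True, True, True, False, False, False],
                        index=list("abcdef"))
    keep = trim_by_overlap(ps, treated)
    # exposure range [0.2, 0.9], control range [0.1, 0.8]
    assert not keep["b"] and not keep["c"]  # exposure above control max 0.8
    assert not keep["d"] and not keep["e"]  # control below exposure min 0.2
    assert keep["a"] and keep["f"]  # boundaries inclusive

    # identical ranges: nobody removed
    ps2 = pd.Series([0.2, 0.8, 0.2, 0.8], index=list("wxyz"))
    t2 = pd.Series([True, True, False, False], index=list("wxyz"))
    assert trim_by_overlap(ps2, t2).all()

    # double-scan oracle on fitted synthetic scores
    db, _ = small_perfect_db
    cohort, _ = build_cohort(db, codes)
    cov = derive_covariates(cohort, db, codes)
    treated = cohort.set_index("patient_id")["group"].eq("exposure")
    res = fit_propensity_model(cov, treated)
    keep = trim_by_overlap(res, treated)
    lo_e, hi_e = res.ps[treated].min(), res.ps[treated].max()
    lo_c, hi_c = res.ps[~treated].min(), res.ps[~treated].max()
    for pid in res.ps.index:
        s = res.ps[pid]
        expected = (lo_c <= s <= hi_c) if treated[pid] else (lo_e <= s <= hi_e)
        assert keep[pid] == expected


@pytest.mark.parametrize("p1,p2,expected", [
    (129 / 321, 179 / 319, -0.323),
    (167 / 321, 86 / 319, 0.530),
    (135 / 321, 48 / 319, 0.627),
    (6 / 321, 20 / 319, -0.224),
    (45 / 321, 49 / 319, -0.038),
    (320 / 321, 319 / 319, -0.079),
])
def test_binary_standardized_differences_published_rows(p1, p2, expected):
    assert round(standardized_difference(p1, p2, "binary"), 3) == expected


def test_continuous_standardized_difference_published_row():
    d = standardized_difference((27.58, 24.58), (22.18, 28.76), "continuous")
    assert round(d, 3) == 0.202


def test_standardized_difference_antisymmetry_and_degenerate():
    assert standardized_difference(0.3, 0.5, "binary") == pytest.approx(
        -standardized_difference(0.5, 0.3, "binary"))
    assert standardized_difference((1.0, 0.0), (1.0, 0.0)) == 0.0
    assert standardized_difference((2.0, 0.0), (1.0, 0.0)) == np.inf


def test_weighted_mean_sd_hand_oracle():
    x = pd.Series([1.0, 2.0, 4.0])
    w = pd.Series([2.0, 1.0, 1.0])
    m, s = weighted_mean_sd(x, w)
    assert m == pytest.approx(2.0)
    # freq-weight variance: sum w (x-m)^2 / (sum w - 1) = (2+0+4)/3
    assert s == pytest.approx(np.sqrt(2.0))


def test_balance_identity_with_unit_weights(small_perfect_db, codes):
    db, _ = small_perfect_db
    cohort, _ = build_cohort(db, codes)
    cov = derive_covariates(cohort, db, codes)
    treated = cohort.set_index("patient_id")["group"].eq("exposure")
    tab = balance_table(cov, treated, unadjusted_weights(treated).weights)
    assert np.allclose(tab["d_unadj"], tab["d_adj"], equal_nan=True)


def test_smrw_balances_confounded_synthetic_cohort(codes):
    """Designed confounding: max unadjusted |d| > 0.3, all adjusted < 0.1."""
    from claimscohort.simulate import SimulationParameters, generate_claims_database

    db, _ = generate_claims_database(SimulationParameters(n_patients=5000, seed=77))
    cohort, _ = build_cohort(db, codes)
    cov = derive_covariates(cohort, db, codes)
    treated = cohort.set_index("patient_id")["group"].eq("exposure")
    wa = smr_weights(fit_propensity_model(cov, treated), treated)
    tab = balance_table(cov.drop(columns=["female"]), treated, wa.weights)
    assert tab["d_unadj"].abs().max() > 0.3
    assert tab["d_adj"].abs().max() < 0.1
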