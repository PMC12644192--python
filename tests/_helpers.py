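"""Hand-built tiny claims databases for unit tests."""

from __future__ import annotations

import pandas as pd

from claimscohort.claims import ClaimsDatabase, TABLE_COLUMNS, empty_database


def make_db(
    patients=(),
    diagnoses=(),
    drugs=(),
    hospitalizations=(),
    labs=(),
    procedures=(),
    data_period=("2012-01-01", "2022-12-31"),
    validate=True,
) -> ClaimsDatabase:
    """Build a typed ClaimsDatabase from lists of row dicts.

    Missing optional fields get sensible defaults; dates may be given as
    strings.
    """
    defaults = {
        "patients": {"sex": "female", "birth_year": 1960,
                     "first_record_date": "2015-01-01", "last_visit_date": "2022-12-01"},
        "diagnoses": {"suspected": False, "primary_for_hospitalization": False,
                      "linked_hospitalization_id": None},
        "drugs": {"route": "intravenous", "dose_mg": 100.0, "setting": "outpatient"},
        "hospitalizations": {},
        "labs": {"test_code": "IMT01", "category": "immunological_infection"},
        "procedures": {"procedure_code": "PRC", "category": "other"},
    }
    base = empty_database(data_period)
    tables = {}
    for name, rows in [
        ("patients", patients), ("diagnoses", diagnoses), ("drugs", drugs),
        ("hospitalizations", hospitalizations), ("labs", labs),
        ("procedures", procedures),
    ]:
        if not rows:
            tables[name] = base.tables[name]
            continue
        full = [{**defaults[name], **row} for row in rows]
        df = pd.DataFrame(full)[TABLE_COLUMNS[name]]
        for col in df.columns:
            if col.endswith("_date"):
                df[col] = pd.to_datetime(df[col])
        if name == "diagnoses":
            df["diagnosis_month"] = pd.PeriodIndex(df["diagnosis_month"], freq="M")
            df["suspected"] = df["suspected"].astype(bool)
            df["primary_for_hospitalization"] = (
                df["primary_for_hospitalization"].astype(bool))
        if name == "drugs":
            df["dose_mg"] = df["dose_mg"].astype(float)
        tables[name] = df
    db = ClaimsDatabase(
        data_period=(pd.Timestamp(data_period[0]), pd.Timestamp(data_period[1])),
        **tables)
    if validate:
        db.validate()
    return db


def patient(pid, first="2015-01-01", last="2022-12-01", birth=1960, sex="female"):
    return {"patient_id": pid, "first_record_date": first, "last_visit_date": last,
            "birth_year": birth, "sex": sex}


def bc_dx(pid, month, code="C50.1", **kw):
    return {"patient_id": pid, "code": code, "diagnosis_month": month, **kw}


def drug(pid, code, date, dose=100.0, **kw):
    return {"patient_id": pid, "drug_code": code, "administration_date": date,
            "dose_mg": dose, **kw}
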