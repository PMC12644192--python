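"""Claims data model: table schemas, code lists, and delimited-text I/O.

The in-memory container for a claims extract is :class:`ClaimsDatabase`, a
bundle of six pandas DataFrames (patients, diagnoses, drugs,
hospitalizations, labs, procedures) plus the data period.  The layout is a
minimal reconstruction of a hospital-based administrative claims extract:
diagnoses carry *month* granularity with a confirmed/suspected flag and an
optional link to the hospitalization they were the primary reason for;
every other event carries day granularity.

Files are UTF-8 comma-delimited with one header row; dates are ISO 8601
(``YYYY-MM-DD``, months ``YYYY-MM``).  The writer/reader pair round-trips
every field exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "ClaimsDatabase",
    "CodeList",
    "CodeLists",
    "ComorbidityEntry",
    "IntegrityError",
    "SchemaError",
    "default_code_lists",
    "load_claims_database",
    "load_code_lists",
    "match_codes",
    "write_claims_database",
]

SCHEMA_VERSION = "1.0"

SEXES = ("female", "male")
ROUTES = ("intravenous", "oral", "other")
SETTINGS = ("inpatient", "outpatient")
LAB_CATEGORIES = ("immunological_infection", "other")
PROCEDURE_CATEGORIES = (
    "breast_cancer_surgery",
    "other_surgery",
    "radiotherapy",
    "pathological_diagnosis",
    "other",
)

#: table name -> ordered column list
TABLE_COLUMNS: dict[str, list[str]] = {
    "patients": ["patient_id", "sex", "birth_year", "first_record_date", "last_visit_date"],
    "diagnoses": [
        "patient_id",
        "code",
        "diagnosis_month",
        "suspected",
        "primary_for_hospitalization",
        "linked_hospitalization_id",
    ],
    "drugs": ["patient_id", "drug_code", "administration_date", "route", "dose_mg", "setting"],
    "hospitalizations": ["hospitalization_id", "patient_id", "admission_date", "discharge_date"],
    "labs": ["patient_id", "test_code", "test_date", "category"],
    "procedures": ["patient_id", "procedure_code", "procedure_date", "category"],
}

_DATE_COLUMNS: dict[str, list[str]] = {
    "patients": ["first_record_date", "last_visit_date"],
    "diagnoses": [],
    "drugs": ["administration_date"],
    "hospitalizations": ["admission_date", "discharge_date"],
    "labs": ["test_date"],
    "procedures": ["procedure_date"],
}

_BOOL_COLUMNS: dict[str, list[str]] = {
    "diagnoses": ["suspected", "primary_for_hospitalization"],
}


class SchemaError(ValueError):
    """A file or row does not conform to the documented schema."""


class IntegrityError(ValueError):
    """Referential integrity or a structural invariant is violated."""


@dataclass
class ClaimsDatabase:
    """A linked longitudinal claims extract (six tables + data period)."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    drugs: pd.DataFrame
    hospitalizations: pd.DataFrame
    labs: pd.DataFrame
    procedures: pd.DataFrame
    data_period: tuple[pd.Timestamp, pd.Timestamp]
    row_errors: list[str] = field(default_factory=list)

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "patients": self.patients,
            "diagnoses": self.diagnoses,
            "drugs": self.drugs,
            "hospitalizations": self.hospitalizations,
            "labs": self.labs,
            "procedures": self.procedures,
        }

    def validate(self) -> None:
        """Raise :class:`IntegrityError` on any invariant violation."""
        known_patients = set(self.patients["patient_id"])
        for name in ("diagnoses", "drugs", "hospitalizations", "labs", "procedures"):
            tab = self.tables[name]
            dangling = set(tab["patient_id"]) - known_patients
            if dangling:
                raise IntegrityError(
                    f"{name}: patient_id(s) {sorted(dangling)[:5]} do not resolve to a patient record"
                )
        hosp_ids = set(self.hospitalizations["hospitalization_id"])
        linked = self.diagnoses["linked_hospitalization_id"].dropna()
        dangling = set(linked) - hosp_ids
        if dangling:
            raise IntegrityError(
                f"diagnoses: linked_hospitalization_id(s) {sorted(dangling)[:5]} do not resolve"
            )
        bad = self.diagnoses["primary_for_hospitalization"] & self.diagnoses[
            "linked_hospitalization_id"
        ].isna()
        if bad.any():
            raise IntegrityError(
                "diagnoses: primary_for_hospitalization rows without linked_hospitalization_id"
            )
        p = self.patients
        if len(p) and (p["first_record_date"] > p["last_visit_date"]).any():
            raise IntegrityError("patients: first_record_date after last_visit_date")
        h = self.hospitalizations
        if len(h) and (h["admission_date"] > h["discharge_date"]).any():
            raise IntegrityError("hospitalizations: admission_date after discharge_date")
        if len(self.drugs) and (self.drugs["dose_mg"] <= 0).any():
            raise IntegrityError("drugs: non-positive dose_mg")

    def subset_patients(self, patient_ids: Iterable[str]) -> "ClaimsDatabase":
        """Restrict every table to the given patients (copy)."""
        ids = set(patient_ids)
        out = {
            name: tab[tab["patient_id"].isin(ids)].reset_index(drop=True)
            for name, tab in self.tables.items()
        }
        return ClaimsDatabase(data_period=self.data_period, **out)


def _empty_table(name: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_COLUMNS[name]})
    return _coerce_table(name, df)[0]


def empty_database(
    data_period: tuple[str, str] = ("2012-01-01", "2022-12-31"),
) -> ClaimsDatabase:
    start, end = (pd.Timestamp(d) for d in data_period)
    return ClaimsDatabase(
        patients=_empty_table("patients"),
        diagnoses=_empty_table("diagnoses"),
        drugs=_empty_table("drugs"),
        hospitalizations=_empty_table("hospitalizations"),
        labs=_empty_table("labs"),
        procedures=_empty_table("procedures"),
        data_period=(start, end),
    )


def _coerce_table(name: str, raw: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Convert string columns to typed columns; collect per-row errors."""
    missing = [c for c in TABLE_COLUMNS[name] if c not in raw.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    df = raw[TABLE_COLUMNS[name]].copy()
    errors: list[str] = []
    bad_rows = pd.Series(False, index=df.index)

    for col in _DATE_COLUMNS.get(name, []):
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        for i in df.index[bad]:
            errors.append(f"{name} row {i}: unparseable date {col}={df.at[i, col]!r}")
        bad_rows |= bad | df[col].isna()
        df[col] = parsed
    if name == "diagnoses":
        parsed = pd.PeriodIndex(
            pd.to_datetime(df["diagnosis_month"], format="%Y-%m", errors="coerce"), freq="M"
        )
        bad = parsed.isna() & df["diagnosis_month"].notna()
        for i in df.index[bad]:
            errors.append(
                f"diagnoses row {i}: unparseable month {df.at[i, 'diagnosis_month']!r}"
            )
        bad_rows |= pd.Series(parsed.isna(), index=df.index)
        df["diagnosis_month"] = pd.Series(parsed, index=df.index)
        linked = df["linked_hospitalization_id"]
        df["linked_hospitalization_id"] = np.where(
            linked.notna() & (linked.astype(str) != ""), linked, None)
    for col in _BOOL_COLUMNS.get(name, []):
        mapped = df[col].map({"True": True, "False": False, True: True, False: False})
        bad = mapped.isna()
        for i in df.index[bad]:
            errors.append(f"{name} row {i}: unparseable boolean {col}={df.at[i, col]!r}")
        bad_rows |= bad
        df[col] = mapped.astype("boolean").fillna(False).astype(bool)
    if name == "patients":
        years = pd.to_numeric(df["birth_year"], errors="coerce")
        bad = years.isna()
        for i in df.index[bad]:
            errors.append(f"patients row {i}: unparseable birth_year")
        bad_rows |= bad
        df["birth_year"] = years.fillna(0).astype(int)
    if name == "drugs":
        dose = pd.to_numeric(df["dose_mg"], errors="coerce")
        bad = dose.isna() | (dose <= 0)
        for i in df.index[bad]:
            errors.append(f"drugs row {i}: invalid dose_mg={df.at[i, 'dose_mg']!r}")
        bad_rows |= bad
        df["dose_mg"] = dose

    df = df[~bad_rows].reset_index(drop=True)
    return df, errors


def load_claims_database(
    paths: Mapping[str, str | Path] | str | Path,
    schema_version: str = SCHEMA_VERSION,
    max_row_error_rate: float = 0.0,
) -> ClaimsDatabase:
    """Read and validate a claims database from delimited text files.

    Parameters
    ----------
    paths
        Either a directory containing ``<table>.csv`` for each of the six
        tables (plus optional ``data_period.csv``), or a mapping from table
        name to file path.
    schema_version
        Declared schema version; only ``"1.0"`` is understood.
    max_row_error_rate
        Fraction of unparseable rows tolerated per table before the load is
        considered fatal.  Rejected rows are dropped and reported in
        ``ClaimsDatabase.row_errors``.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {schema_version!r}")
    if isinstance(paths, (str, Path)):
        directory = Path(paths)
        paths = {name: directory / f"{name}.csv" for name in TABLE_COLUMNS}
        period_path = directory / "data_period.csv"
    else:
        paths = {k: Path(v) for k, v in paths.items()}
        period_path = paths.get("data_period")  # type: ignore[assignment]

    tables: dict[str, pd.DataFrame] = {}
    all_errors: list[str] = []
    for name in TABLE_COLUMNS:
        path = Path(paths[name])
        if not path.exists():
            raise FileNotFoundError(f"missing claims table file: {path}")
        raw = pd.read_csv(path, dtype=str, keep_default_na=True)
        n_raw = len(raw)
        df, errors = _coerce_table(name, raw)
        all_errors.extend(errors)
        if n_raw and (n_raw - len(df)) / n_raw > max_row_error_rate and errors:
            raise SchemaError(
                f"{name}: {n_raw - len(df)}/{n_raw} rows rejected "
                f"(> max_row_error_rate={max_row_error_rate}); first error: {errors[0]}"
            )
        tables[name] = df

    if period_path is not None and Path(period_path).exists():
        per = pd.read_csv(period_path, dtype=str)
        period = (pd.Timestamp(per.at[0, "start"]), pd.Timestamp(per.at[0, "end"]))
    else:
        dates = [
            tables[n][c] for n in TABLE_COLUMNS for c in _DATE_COLUMNS.get(n, []) if len(tables[n])
        ]
        if dates:
            allc = pd.concat(dates)
            period = (allc.min(), allc.max())
        else:
            period = (pd.Timestamp("2012-01-01"), pd.Timestamp("2022-12-31"))

    db = ClaimsDatabase(data_period=period, row_errors=all_errors, **tables)
    db.validate()
    return db


def write_claims_database(db: ClaimsDatabase, directory: str | Path) -> dict[str, Path]:
    """Write all six tables (plus ``data_period.csv``) as CSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, tab in db.tables.items():
        out = tab.copy()
        for col in _DATE_COLUMNS.get(name, []):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
        if name == "diagnoses":
            out["diagnosis_month"] = out["diagnosis_month"].astype(str)
        path = directory / f"{name}.csv"
        out.to_csv(path, index=False)
        written[name] = path
    period = pd.DataFrame(
        {
            "start": [db.data_period[0].strftime("%Y-%m-%d")],
            "end": [db.data_period[1].strftime("%Y-%m-%d")],
        }
    )
    period_path = directory / "data_period.csv"
    period.to_csv(period_path, index=False)
    written["data_period"] = period_path
    return written


# ---------------------------------------------------------------------------
# Code lists


class CodeList(BaseModel):
    """A set of code patterns with declared matching semantics.

    ``prefix`` matching treats each pattern as a code-family prefix (the
    natural semantics for hierarchical diagnosis codes, where ``C50``
    matches ``C50.9``); ``exact`` matching requires identity (flat drug or
    procedure code lists).
    """

    codes: list[str] = Field(default_factory=list)
    match: Literal["exact", "prefix"] = "exact"

    def covers(self, pattern: str) -> bool:
        if self.match == "prefix":
            return any(pattern.startswith(p) for p in self.codes)
        return pattern in self.codes


def match_codes(values: pd.Series, code_list: CodeList) -> pd.Series:
    """Boolean mask of ``values`` matching ``code_list`` under its semantics."""
    if not len(values):
        return pd.Series(dtype=bool)
    values = values.astype(str)
    if code_list.match == "prefix":
        if not code_list.codes:
            return pd.Series(False, index=values.index)
        return values.str.startswith(tuple(code_list.codes))
    return values.isin(code_list.codes)


class ComorbidityEntry(BaseModel):
    """One comorbidity-index category: code pattern, category label, weight."""

    pattern: str
    category: str
    weight: int
    match: Literal["exact", "prefix"] = "prefix"


class CodeLists(BaseModel):
    """All configurable code lists used by the pipeline.

    The diagnosis lists default to prefix semantics and the drug/procedure
    lists to exact semantics.  ``covid19`` must be a sub-family of
    ``infection``; the study-drug code sets must be disjoint from
    ``other_anticancer``.
    """

    breast_cancer: CodeList
    her2_positive: CodeList
    infection: CodeList
    covid19: CodeList
    iv_antibacterial: CodeList
    study_drug: dict[str, CodeList]  # keys: atezolizumab, nab_paclitaxel
    other_anticancer: CodeList
    adjuvant_chemo: CodeList = CodeList()
    other_regimen: CodeList = CodeList()
    anticancer_history: CodeList = CodeList()
    steroid: CodeList = CodeList()
    covariate_diagnosis: dict[str, CodeList] = Field(default_factory=dict)
    comorbidity_map: list[ComorbidityEntry] = Field(default_factory=list)

    @field_validator("breast_cancer", "infection", "iv_antibacterial")
    @classmethod
    def _mandatory_nonempty(cls, v: CodeList, info) -> CodeList:
        if not v.codes:
            raise ValueError(f"mandatory code list {info.field_name!r} is empty")
        return v

    @model_validator(mode="after")
    def _invariants(self) -> "CodeLists":
        for code in self.covid19.codes:
            if not self.infection.covers(code):
                raise ValueError(
                    f"covid19 code {code!r} is not covered by the infection list"
                )
        for drug in ("atezolizumab", "nab_paclitaxel"):
            if drug not in self.study_drug:
                raise ValueError(f"study_drug mapping lacks {drug!r}")
            overlap = set(self.study_drug[drug].codes) & set(self.other_anticancer.codes)
            if overlap:
                raise ValueError(
                    f"study drug codes {sorted(overlap)} also listed as other_anticancer"
                )
        return self


def load_code_lists(config_path: str | Path) -> CodeLists:
    """Load a :class:`CodeLists` configuration from a YAML file."""
    with open(config_path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "code_lists" not in raw:
        raise SchemaError("code-list config must contain a 'code_lists' mapping")
    return CodeLists.model_validate(raw["code_lists"])


def default_code_lists() -> CodeLists:
    """The synthetic placeholder code lists shipped with the package.

    Stand-ins for proprietary code dictionaries: structurally faithful
    (hierarchical diagnosis prefixes, flat drug codes, a 17-category
    comorbidity weight map) but with invented code values.
    """
    from importlib.resources import files

    path = files("claimscohort.data").joinpath("default_code_lists.yaml")
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    return CodeLists.model_validate(raw["code_lists"])
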