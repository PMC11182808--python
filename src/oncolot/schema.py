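"""Claims data model, calendar conventions, and CSV readers/writers.

The in-memory container is :class:`ClaimsBundle`, a set of four pandas
DataFrames mirroring the table structure of Japanese hospital claims
databases: a patient table (demographics, death date, last hospital visit),
monthly diagnosis records carrying ICD-10 codes, exact-date drug
prescriptions with remuneration points and care setting, and dated
procedures (surgery, receptor tests, other point-bearing claims).

Dates are calendar dates (``datetime64[ns]``); diagnoses carry a calendar
year-month only (``Period[M]``), because Japanese claims diagnoses are
recorded at monthly granularity.  All intervals in days are calendar-day
differences and every window is closed unless stated otherwise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Days per month used whenever a day count is reported in months
#: (365.25 / 12, the standard survival-analysis convention).
DAYS_PER_MONTH = 30.4375

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9]?$")

SEXES = ("female", "male")
SETTINGS = ("inpatient", "outpatient")

PATIENT_COLUMNS = ["patient_id", "sex", "birth_year", "death_date", "last_visit_date"]
DIAGNOSIS_COLUMNS = ["patient_id", "month", "icd10_code", "suspected_flag"]
PRESCRIPTION_COLUMNS = ["patient_id", "date", "drug_code", "setting", "points"]
PROCEDURE_COLUMNS = ["patient_id", "date", "procedure_code", "setting", "points"]

TABLE_FILES = {
    "patients": "patients.csv",
    "diagnoses": "diagnoses.csv",
    "prescriptions": "prescriptions.csv",
    "procedures": "procedures.csv",
}


class ClaimsValidationError(ValueError):
    """Raised when a bundle violates the schema; carries row-level messages."""

    def __init__(self, problems: Iterable[str]):
        self.problems = list(problems)
        preview = "\n".join(self.problems[:20])
        more = "" if len(self.problems) <= 20 else f"\n... and {len(self.problems) - 20} more"
        super().__init__(f"{len(self.problems)} validation problem(s):\n{preview}{more}")


@dataclass
class ClaimsBundle:
    """Validated container for the four claims tables plus the data period."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    procedures: pd.DataFrame
    data_start: pd.Timestamp
    data_end: pd.Timestamp

    def copy(self) -> "ClaimsBundle":
        return ClaimsBundle(
            self.patients.copy(),
            self.diagnoses.copy(),
            self.prescriptions.copy(),
            self.procedures.copy(),
            self.data_start,
            self.data_end,
        )

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def validate(self) -> None:
        """Re-check every schema invariant; raise ClaimsValidationError on failure."""
        problems = _validate_tables(
            self.patients, self.diagnoses, self.prescriptions, self.procedures,
            self.data_start, self.data_end,
        )
        if problems:
            raise ClaimsValidationError(problems)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (0.5 rounds away from zero), as printed tables use."""
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def days_to_months(days) -> float:
    """Convert a positive day count to months (days / 30.4375).

    Accepts a scalar or array; every value must be >= 1.
    """
    arr = np.asarray(days, dtype=float)
    if np.any(arr < 1):
        raise ValueError("day counts must be >= 1")
    out = arr / DAYS_PER_MONTH
    return float(out) if np.isscalar(days) or arr.ndim == 0 else out


def same_or_previous_month(event_month, reference_date) -> bool:
    """True iff *event_month* is the calendar month of *reference_date* or the one before."""
    month = pd.Period(event_month, freq="M")
    ref = pd.Timestamp(reference_date).to_period("M")
    return month == ref or month == ref - 1


# ---------------------------------------------------------------------------
# Table-level coercion and validation


def _coerce_patients(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["sex"] = df["sex"].astype(str).str.strip()
    df["birth_year"] = pd.to_numeric(df["birth_year"], errors="coerce").astype("Int64")
    df["death_date"] = pd.to_datetime(df["death_date"], errors="coerce", format="ISO8601")
    df["last_visit_date"] = pd.to_datetime(df["last_visit_date"], errors="coerce", format="ISO8601")
    return df[PATIENT_COLUMNS]


def _coerce_diagnoses(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["month"] = pd.PeriodIndex(df["month"].astype(str), freq="M") if len(df) else pd.PeriodIndex([], freq="M")
    df["icd10_code"] = df["icd10_code"].astype(str).str.strip()
    df["suspected_flag"] = df["suspected_flag"].map(_parse_bool)
    return df[DIAGNOSIS_COLUMNS]


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no", ""):
        return False
    raise ValueError(f"unparseable boolean: {v!r}")


def _coerce_claims(df: pd.DataFrame, code_col: str, columns: list[str]) -> pd.DataFrame:
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["date"] = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    df[code_col] = df[code_col].astype(str).str.strip()
    df["setting"] = df["setting"].astype(str).str.strip()
    df["points"] = pd.to_numeric(df["points"], errors="coerce")
    return df[columns]


def _validate_tables(patients, diagnoses, prescriptions, procedures, data_start, data_end):
    problems: list[str] = []
    if not data_start < data_end:
        problems.append(f"data_start {data_start.date()} must precede data_end {data_end.date()}")

    ids = patients["patient_id"]
    dup = ids[ids.duplicated()]
    for i in dup.index:
        problems.append(f"patients row {i}: duplicate patient_id {ids[i]!r}")
    bad_sex = patients.index[~patients["sex"].isin(SEXES)]
    for i in bad_sex:
        problems.append(f"patients row {i}: sex must be one of {SEXES}, got {patients['sex'][i]!r}")
    for i in patients.index[patients["birth_year"].isna()]:
        problems.append(f"patients row {i}: missing/unparseable birth_year")
    for i in patients.index[patients["last_visit_date"].isna()]:
        problems.append(f"patients row {i}: last_visit_date is mandatory")
    has_death = patients["death_date"].notna()
    if has_death.any():
        by_floor = pd.to_datetime(patients.loc[has_death, "birth_year"].astype(int).astype(str) + "-01-01")
        early = patients.index[has_death][patients.loc[has_death, "death_date"].to_numpy() < by_floor.to_numpy()]
        for i in early:
            problems.append(f"patients row {i}: death_date precedes birth year")
        late = patients.index[has_death & (patients["death_date"] > data_end)]
        for i in late:
            problems.append(f"patients row {i}: death_date after data_end")

    known = set(ids)
    for name, df in (("diagnoses", diagnoses), ("prescriptions", prescriptions), ("procedures", procedures)):
        unknown = df.index[~df["patient_id"].isin(known)]
        for i in unknown:
            problems.append(f"{name} row {i}: unknown patient_id {df['patient_id'][i]!r}")

    bad_code = diagnoses.index[~diagnoses["icd10_code"].str.match(_ICD10_RE)]
    for i in bad_code:
        problems.append(f"diagnoses row {i}: icd10_code {diagnoses['icd10_code'][i]!r} not ICD-10-shaped")
    if len(diagnoses):
        lo, hi = data_start.to_period("M"), data_end.to_period("M")
        out = diagnoses.index[(diagnoses["month"] < lo) | (diagnoses["month"] > hi)]
        for i in out:
            problems.append(f"diagnoses row {i}: month {diagnoses['month'][i]} outside data period")

    for name, df in (("prescriptions", prescriptions), ("procedures", procedures)):
        for i in df.index[df["date"].isna()]:
            problems.append(f"{name} row {i}: missing/unparseable date")
        inside = df["date"].between(data_start, data_end)
        for i in df.index[df["date"].notna() & ~inside]:
            problems.append(f"{name} row {i}: date {df['date'][i].date()} outside data period")
        for i in df.index[~df["setting"].isin(SETTINGS)]:
            problems.append(f"{name} row {i}: setting must be one of {SETTINGS}, got {df['setting'][i]!r}")
        for i in df.index[df["points"].isna() | (df["points"] < 0)]:
            problems.append(f"{name} row {i}: points must be a number >= 0")

    return problems


def make_bundle(patients, diagnoses, prescriptions, procedures, data_start, data_end,
                validate: bool = True) -> ClaimsBundle:
    """Coerce raw frames to the schema dtypes and (optionally) validate."""
    bundle = ClaimsBundle(
        _coerce_patients(pd.DataFrame(patients, columns=PATIENT_COLUMNS)),
        _coerce_diagnoses(pd.DataFrame(diagnoses, columns=DIAGNOSIS_COLUMNS)),
        _coerce_claims(pd.DataFrame(prescriptions, columns=PRESCRIPTION_COLUMNS),
                       "drug_code", PRESCRIPTION_COLUMNS),
        _coerce_claims(pd.DataFrame(procedures, columns=PROCEDURE_COLUMNS),
                       "procedure_code", PROCEDURE_COLUMNS),
        pd.Timestamp(data_start),
        pd.Timestamp(data_end),
    )
    if validate:
        bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# CSV I/O


def read_claims_bundle(paths: Mapping[str, Path] | Path | str,
                       data_start=None, data_end=None,
                       validate: bool = True) -> ClaimsBundle:
    """Read the four claims CSVs into a validated :class:`ClaimsBundle`.

    *paths* is either a directory containing the conventionally named files
    (``patients.csv`` etc.) or a mapping from table name to file path.  The
    data period defaults to the span of dates observed in the tables; pass
    *data_start*/*data_end* to pin it.
    """
    if not isinstance(paths, Mapping):
        root = Path(paths)
        paths = {k: root / v for k, v in TABLE_FILES.items()}
    missing = [str(p) for p in paths.values() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing claims table file(s): {', '.join(missing)}")

    raw = {k: pd.read_csv(paths[k], dtype=str, keep_default_na=False).replace({"": None})
           for k in TABLE_FILES}
    for k in TABLE_FILES:
        expected = {"patients": PATIENT_COLUMNS, "diagnoses": DIAGNOSIS_COLUMNS,
                    "prescriptions": PRESCRIPTION_COLUMNS, "procedures": PROCEDURE_COLUMNS}[k]
        got = list(raw[k].columns)
        if got != expected:
            raise ClaimsValidationError([f"{k}: expected header {expected}, got {got}"])

    patients = _coerce_patients(raw["patients"])
    diagnoses = _coerce_diagnoses(raw["diagnoses"])
    prescriptions = _coerce_claims(raw["prescriptions"], "drug_code", PRESCRIPTION_COLUMNS)
    procedures = _coerce_claims(raw["procedures"], "procedure_code", PROCEDURE_COLUMNS)

    if data_start is None or data_end is None:
        stamps = [patients["last_visit_date"].min(), prescriptions["date"].min(),
                  procedures["date"].min()]
        if len(diagnoses):
            stamps.append(diagnoses["month"].min().to_timestamp())
        lo = min((s for s in stamps if pd.notna(s)), default=pd.Timestamp("2000-01-01"))
        stamps = [patients["last_visit_date"].max(), patients["death_date"].max(),
                  prescriptions["date"].max(), procedures["date"].max()]
        if len(diagnoses):
            stamps.append(diagnoses["month"].max().to_timestamp(how="end").normalize())
        hi = max((s for s in stamps if pd.notna(s)), default=pd.Timestamp("2000-12-31"))
        data_start = data_start if data_start is not None else lo
        data_end = data_end if data_end is not None else hi

    bundle = ClaimsBundle(patients, diagnoses, prescriptions, procedures,
                          pd.Timestamp(data_start), pd.Timestamp(data_end))
    if validate:
        bundle.validate()
    return bundle


def write_claims_bundle(bundle: ClaimsBundle, out_dir: Path | str) -> dict[str, Path]:
    """Write the four tables as UTF-8 CSVs under *out_dir*; return the path map.

    ``read_claims_bundle(write_claims_bundle(b))`` reproduces *b* field for
    field (absent death dates round-trip as empty cells).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in TABLE_FILES.items()}

    pat = bundle.patients.copy()
    for col in ("death_date", "last_visit_date"):
        pat[col] = pat[col].dt.strftime("%Y-%m-%d")
    pat.to_csv(paths["patients"], index=False)

    dx = bundle.diagnoses.copy()
    dx["month"] = dx["month"].astype(str)
    dx["suspected_flag"] = dx["suspected_flag"].map({True: "true", False: "false"})
    dx.to_csv(paths["diagnoses"], index=False)

    for key in ("prescriptions", "procedures"):
        df = getattr(bundle, key).copy()
        df["date"] = df["date"].dt.strftime("%Y-%m-%d")
        df.to_csv(paths[key], index=False)
    return paths
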