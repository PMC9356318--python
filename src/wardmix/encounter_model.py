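"""Domain model for hospital encounter data, with CSV I/O and validation.

The unit of analysis is the *admission* (one hospitalization of one
patient); a patient readmitted twice contributes two admissions.  Each
admission carries demographics (age in years, top-coded at 90; sex; an
Elixhauser comorbidity score 0-16) and is linked to one or more unit stays
(intervals of calendar days spent in a named hospital unit) and zero or
more antibiotic-exposure records (one row per day per spectrum rank).

All dates are day-granular ISO-8601.  Stay intervals are inclusive on both
ends: a stay [d, d] contributes the single day d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

#: Antibiotic spectrum ranks, ordered from narrowest to most restricted.
ABX_RANKS = ("narrow", "broad", "extended", "protected")

#: Allowed sex tokens; missingness is explicit, never an empty cell.
SEX_LEVELS = ("F", "M", "missing")

AGE_MAX = 90
ELIX_MAX = 16

ADMISSIONS_COLUMNS = [
    "admission_id",
    "patient_id",
    "hospital_id",
    "age",
    "sex",
    "elixhauser",
    "admit_date",
    "discharge_date",
]
STAYS_COLUMNS = ["admission_id", "unit_id", "unit_type", "entry_date", "exit_date"]
EXPOSURES_COLUMNS = ["admission_id", "date", "rank"]

#: CSV token used for missing sex; restored as "missing" on read.
_SEX_NA_TOKEN = "NA"


class EncounterDataError(Exception):
    """Base class for encounter-data loading errors."""


class SchemaError(EncounterDataError):
    """A required column is missing or mis-named."""


class RowParseError(EncounterDataError):
    """A cell could not be parsed; carries the offending line number."""


class ReferentialError(EncounterDataError):
    """A stay or exposure references an admission_id that does not exist."""


class DomainError(EncounterDataError):
    """A categorical value is outside its allowed levels."""


@dataclass(frozen=True)
class Admission:
    admission_id: str
    patient_id: str
    hospital_id: str
    age: int
    sex: str
    elixhauser: int
    admit_date: date
    discharge_date: date


@dataclass(frozen=True)
class UnitStay:
    admission_id: str
    unit_id: str
    unit_type: str
    entry_date: date
    exit_date: date  # inclusive

    @property
    def n_days(self) -> int:
        return (self.exit_date - self.entry_date).days + 1


@dataclass(frozen=True)
class AbxExposure:
    admission_id: str
    date: date
    rank: str


@dataclass
class EncounterBundle:
    """A self-contained collection of admissions, unit stays and exposures."""

    admissions: list[Admission] = field(default_factory=list)
    stays: list[UnitStay] = field(default_factory=list)
    exposures: list[AbxExposure] = field(default_factory=list)

    def admission_index(self) -> dict[str, Admission]:
        return {a.admission_id: a for a in self.admissions}

    def hospital_ids(self) -> list[str]:
        return sorted({a.hospital_id for a in self.admissions})

    def stays_for_hospital(self, hospital_id: str) -> list[UnitStay]:
        member = {
            a.admission_id for a in self.admissions if a.hospital_id == hospital_id
        }
        return [s for s in self.stays if s.admission_id in member]


@dataclass(frozen=True)
class Violation:
    """One invariant violation, keyed by the offending record."""

    record_key: str
    rule: str
    message: str


ValidationReport = list[Violation]


def _check_columns(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def _parse_date(token: str, path: str, line: int, col: str) -> date:
    try:
        return date.fromisoformat(str(token).strip())
    except ValueError as exc:
        raise RowParseError(
            f"{path}, line {line}: cannot parse {col}={token!r} as ISO-8601 date"
        ) from exc


def _parse_int(token: str, path: str, line: int, col: str) -> int:
    try:
        return int(str(token).strip())
    except ValueError as exc:
        raise RowParseError(
            f"{path}, line {line}: cannot parse {col}={token!r} as integer"
        ) from exc


def _read_csv(path) -> pd.DataFrame:
    # keep_default_na=False so the sex token "NA" survives as a string
    return pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])


def read_bundle(admissions_path, stays_path, exposures_path) -> EncounterBundle:
    """Load and structurally validate the three encounter CSV files.

    Raises
    ------
    SchemaError
        if a required column is absent.
    RowParseError
        if a date or integer cell cannot be parsed (names the line).
    ReferentialError
        if a stay or exposure references an unknown admission_id.
    DomainError
        if sex or antibiotic rank is outside its allowed levels.
    """
    adm_df = _read_csv(admissions_path)
    stay_df = _read_csv(stays_path)
    exp_df = _read_csv(exposures_path)
    _check_columns(adm_df, ADMISSIONS_COLUMNS, str(admissions_path))
    _check_columns(stay_df, STAYS_COLUMNS, str(stays_path))
    _check_columns(exp_df, EXPOSURES_COLUMNS, str(exposures_path))

    admissions: list[Admission] = []
    for i, row in enumerate(adm_df.itertuples(index=False)):
        line = i + 2  # header is line 1
        sex = str(row.sex).strip()
        if sex == _SEX_NA_TOKEN:
            sex = "missing"
        if sex not in SEX_LEVELS:
            raise DomainError(
                f"{admissions_path}, line {line}: sex={row.sex!r} not in {SEX_LEVELS}"
            )
        admissions.append(
            Admission(
                admission_id=str(row.admission_id),
                patient_id=str(row.patient_id),
                hospital_id=str(row.hospital_id),
                age=_parse_int(row.age, str(admissions_path), line, "age"),
                sex=sex,
                elixhauser=_parse_int(
                    row.elixhauser, str(admissions_path), line, "elixhauser"
                ),
                admit_date=_parse_date(
                    row.admit_date, str(admissions_path), line, "admit_date"
                ),
                discharge_date=_parse_date(
                    row.discharge_date, str(admissions_path), line, "discharge_date"
                ),
            )
        )

    known = {a.admission_id for a in admissions}

    stays: list[UnitStay] = []
    for i, row in enumerate(stay_df.itertuples(index=False)):
        line = i + 2
        aid = str(row.admission_id)
        if aid not in known:
            raise ReferentialError(
                f"{stays_path}, line {line}: admission_id {aid!r} not present "
                f"in admissions table"
            )
        stays.append(
            UnitStay(
                admission_id=aid,
                unit_id=str(row.unit_id),
                unit_type=str(row.unit_type),
                entry_date=_parse_date(
                    row.entry_date, str(stays_path), line, "entry_date"
                ),
                exit_date=_parse_date(row.exit_date, str(stays_path), line, "exit_date"),
            )
        )

    exposures: list[AbxExposure] = []
    for i, row in enumerate(exp_df.itertuples(index=False)):
        line = i + 2
        aid = str(row.admission_id)
        if aid not in known:
            raise ReferentialError(
                f"{exposures_path}, line {line}: admission_id {aid!r} not present "
                f"in admissions table"
            )
        rank = str(row.rank).strip()
        if rank not in ABX_RANKS:
            raise DomainError(
                f"{exposures_path}, line {line}: rank={rank!r} not one of {ABX_RANKS}"
            )
        exposures.append(
            AbxExposure(
                admission_id=aid,
                date=_parse_date(row.date, str(exposures_path), line, "date"),
                rank=rank,
            )
        )

    return EncounterBundle(admissions=admissions, stays=stays, exposures=exposures)


def validate_bundle(bundle: EncounterBundle) -> ValidationReport:
    """Check every type invariant; return a deterministic, ordered report.

    Violations are reported, never thrown; an empty report means the bundle
    satisfies all invariants.  The report is sorted by record key then rule
    so repeated calls are identical.
    """
    report: ValidationReport = []
    seen_ids: set[str] = set()
    index = bundle.admission_index()

    for a in bundle.admissions:
        key = a.admission_id
        if key in seen_ids:
            report.append(Violation(key, "unique_admission_id", "duplicate admission_id"))
        seen_ids.add(key)
        if not (0 <= a.age <= AGE_MAX):
            report.append(Violation(key, "age_range", f"age {a.age} out of [0,{AGE_MAX}]"))
        if not (0 <= a.elixhauser <= ELIX_MAX):
            report.append(
                Violation(
                    key, "elixhauser_range", f"elixhauser {a.elixhauser} out of [0,{ELIX_MAX}]"
                )
            )
        if a.sex not in SEX_LEVELS:
            report.append(Violation(key, "sex_level", f"sex {a.sex!r} not in {SEX_LEVELS}"))
        if a.admit_date > a.discharge_date:
            report.append(
                Violation(key, "date_order", "admit_date after discharge_date")
            )

    seen_stays: set[tuple[str, str, date]] = set()
    for s in bundle.stays:
        key = f"{s.admission_id}/{s.unit_id}/{s.entry_date.isoformat()}"
        if s.entry_date > s.exit_date:
            report.append(Violation(key, "stay_date_order", "exit_date before entry_date"))
        parent = index.get(s.admission_id)
        if parent is None:
            report.append(Violation(key, "stay_fk", "admission_id not found"))
        elif not (parent.admit_date <= s.entry_date and s.exit_date <= parent.discharge_date):
            report.append(
                Violation(key, "stay_within_admission", "stay outside admission interval")
            )
        dup_key = (s.admission_id, s.unit_id, s.entry_date)
        if dup_key in seen_stays:
            report.append(Violation(key, "duplicate_stay", "duplicate stay row"))
        seen_stays.add(dup_key)

    for e in bundle.exposures:
        key = f"{e.admission_id}/{e.date.isoformat()}/{e.rank}"
        if e.rank not in ABX_RANKS:
            report.append(Violation(key, "rank_level", f"rank {e.rank!r} not in {ABX_RANKS}"))
        parent = index.get(e.admission_id)
        if parent is None:
            report.append(Violation(key, "exposure_fk", "admission_id not found"))
        elif not (parent.admit_date <= e.date <= parent.discharge_date):
            report.append(
                Violation(key, "exposure_within_admission", "exposure date outside stay")
            )

    report.sort(key=lambda v: (v.record_key, v.rule))
    return report


def bundle_to_frames(
    bundle: EncounterBundle,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Represent a bundle as three pandas DataFrames in the fixed schema."""
    adm = pd.DataFrame(
        [
            {
                "admission_id": a.admission_id,
                "patient_id": a.patient_id,
                "hospital_id": a.hospital_id,
                "age": a.age,
                "sex": _SEX_NA_TOKEN if a.sex == "missing" else a.sex,
                "elixhauser": a.elixhauser,
                "admit_date": a.admit_date.isoformat(),
                "discharge_date": a.discharge_date.isoformat(),
            }
            for a in bundle.admissions
        ],
        columns=ADMISSIONS_COLUMNS,
    )
    stays = pd.DataFrame(
        [
            {
                "admission_id": s.admission_id,
                "unit_id": s.unit_id,
                "unit_type": s.unit_type,
                "entry_date": s.entry_date.isoformat(),
                "exit_date": s.exit_date.isoformat(),
            }
            for s in bundle.stays
        ],
        columns=STAYS_COLUMNS,
    )
    exp = pd.DataFrame(
        [
            {
                "admission_id": e.admission_id,
                "date": e.date.isoformat(),
                "rank": e.rank,
            }
            for e in bundle.exposures
        ],
        columns=EXPOSURES_COLUMNS,
    )
    return adm, stays, exp


def write_bundle(bundle: EncounterBundle, directory) -> dict[str, Path]:
    """Write admissions.csv, unit_stays.csv, abx_exposures.csv to *directory*.

    Round-trip guarantee: ``read_bundle(**write_bundle(b))`` equals ``b``
    field-for-field.  Missing sex is written as the literal token ``NA``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    adm, stays, exp = bundle_to_frames(bundle)
    paths = {
        "admissions": directory / "admissions.csv",
        "stays": directory / "unit_stays.csv",
        "exposures": directory / "abx_exposures.csv",
    }
    adm.to_csv(paths["admissions"], index=False)
    stays.to_csv(paths["stays"], index=False)
    exp.to_csv(paths["exposures"], index=False)
    return paths


def read_bundle_dir(directory) -> EncounterBundle:
    """Read a bundle from a directory written by :func:`write_bundle`."""
    directory = Path(directory)
    return read_bundle(
        directory / "admissions.csv",
        directory / "unit_stays.csv",
        directory / "abx_exposures.csv",
    )
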