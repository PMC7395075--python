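"""Schema, CSV round-tripping and validation for the PK summary database.

The database holds one row per published study x substrate x route x PK
parameter, exactly as reported in the source publication (arithmetic or
geometric central value, one of four dispersion statistics, the administered
dose and its basis).  Normalisation to a common lognormal scale happens
downstream in :mod:`ugtvar.standardize`; this module only guarantees that
every record is well-typed and internally consistent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "Route",
    "Parameter",
    "DoseBasis",
    "HealthStatus",
    "Regimen",
    "CentralKind",
    "DispersionKind",
    "StudySummaryRecord",
    "PKDatabase",
    "Violation",
    "CSV_COLUMNS",
    "BSA_NORMALISED_SUBSTRATES",
    "read_pk_database",
    "write_pk_database",
    "validate_records",
    "select_analysis_set",
]


class Route(str, enum.Enum):
    ORAL = "oral"
    IV = "iv"


class Parameter(str, enum.Enum):
    AUC = "auc"
    CLEARANCE = "clearance"
    CMAX = "cmax"


class DoseBasis(str, enum.Enum):
    TOTAL_MG = "total_mg"
    MG_PER_KG = "mg_per_kg"
    MG_PER_M2 = "mg_per_m2"


class HealthStatus(str, enum.Enum):
    HEALTHY = "healthy"
    PATIENT = "patient"


class Regimen(str, enum.Enum):
    SINGLE_DOSE = "single_dose"
    REPEATED_21D = "repeated_21d"


class CentralKind(str, enum.Enum):
    AM = "AM"
    GM = "GM"


class DispersionKind(str, enum.Enum):
    SD = "SD"
    SE = "SE"
    CV_FRACTION = "CV_fraction"
    GSD = "GSD"


#: Substrates whose dose is conventionally normalised to body surface area
#: rather than body weight (the SN38 / oncology convention).
BSA_NORMALISED_SUBSTRATES: frozenset[str] = frozenset({"SN38"})

#: Canonical column order of the CSV interchange format.
CSV_COLUMNS: tuple[str, ...] = (
    "study_id",
    "substrate_id",
    "isoform_ids",
    "route",
    "parameter",
    "n_subjects",
    "dose_value",
    "dose_basis",
    "body_weight_kg",
    "bsa_m2",
    "geography",
    "health_status",
    "regimen",
    "central_kind",
    "central_value",
    "dispersion_kind",
    "dispersion_value",
    "value_units",
)


@dataclass(frozen=True)
class StudySummaryRecord:
    """One published study's summary of a PK parameter, as reported."""

    study_id: str
    substrate_id: str
    isoform_ids: tuple[str, ...]
    route: Route
    parameter: Parameter
    n_subjects: int
    dose_value: float
    dose_basis: DoseBasis
    body_weight_kg: float | None
    bsa_m2: float | None
    geography: str
    health_status: HealthStatus
    regimen: Regimen
    central_kind: CentralKind
    central_value: float
    dispersion_kind: DispersionKind
    dispersion_value: float
    value_units: str

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.study_id, self.substrate_id, self.route.value, self.parameter.value)


@dataclass
class PKDatabase:
    """Ordered collection of study summary records."""

    records: list[StudySummaryRecord] = field(default_factory=list)
    schema_version: str = "1.0"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class Violation:
    """A single invariant violation found by :func:`validate_records`."""

    record_index: int
    study_id: str
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"record {self.record_index} ({self.study_id}): {self.field}: {self.rule}"


def _parse_enum(cls, token: str, row: int, column: str):
    try:
        return cls(token)
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise ValueError(
            f"row {row}, column '{column}': unknown token {token!r} (allowed: {allowed})"
        ) from None


def _parse_float(token: str, row: int, column: str, optional: bool = False) -> float | None:
    if token == "":
        if optional:
            return None
        raise ValueError(f"row {row}, column '{column}': missing mandatory value")
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"row {row}, column '{column}': not a number: {token!r}") from None


def read_pk_database(path: str | Path, schema_version: str = "1.0") -> PKDatabase:
    """Read a PK summary database from CSV.

    The header must match :data:`CSV_COLUMNS` exactly.  Every row is parsed
    into a :class:`StudySummaryRecord`; unknown enum tokens, non-numeric or
    missing mandatory values raise :class:`ValueError` naming the offending
    row (1-based, excluding the header) and column.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if tuple(frame.columns) != CSV_COLUMNS:
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        raise ValueError(
            f"header mismatch: expected columns {list(CSV_COLUMNS)}; missing {missing}"
        )
    records: list[StudySummaryRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        r = dict(zip(CSV_COLUMNS, row))
        n_raw = r["n_subjects"]
        try:
            n_subjects = int(n_raw)
        except ValueError:
            raise ValueError(
                f"row {i}, column 'n_subjects': not an integer: {n_raw!r}"
            ) from None
        rec = StudySummaryRecord(
            study_id=r["study_id"],
            substrate_id=r["substrate_id"],
            isoform_ids=tuple(t for t in r["isoform_ids"].split(";") if t),
            route=_parse_enum(Route, r["route"], i, "route"),
            parameter=_parse_enum(Parameter, r["parameter"], i, "parameter"),
            n_subjects=n_subjects,
            dose_value=_parse_float(r["dose_value"], i, "dose_value"),
            dose_basis=_parse_enum(DoseBasis, r["dose_basis"], i, "dose_basis"),
            body_weight_kg=_parse_float(r["body_weight_kg"], i, "body_weight_kg", optional=True),
            bsa_m2=_parse_float(r["bsa_m2"], i, "bsa_m2", optional=True),
            geography=r["geography"],
            health_status=_parse_enum(HealthStatus, r["health_status"], i, "health_status"),
            regimen=_parse_enum(Regimen, r["regimen"], i, "regimen"),
            central_kind=_parse_enum(CentralKind, r["central_kind"], i, "central_kind"),
            central_value=_parse_float(r["central_value"], i, "central_value"),
            dispersion_kind=_parse_enum(DispersionKind, r["dispersion_kind"], i, "dispersion_kind"),
            dispersion_value=_parse_float(r["dispersion_value"], i, "dispersion_value"),
            value_units=r["value_units"],
        )
        for col in ("dose_value", "central_value"):
            if getattr(rec, col) <= 0:
                raise ValueError(f"row {i}, column '{col}': must be positive")
        if rec.n_subjects < 1:
            raise ValueError(f"row {i}, column 'n_subjects': must be >= 1")
        if rec.dispersion_value < 0:
            raise ValueError(f"row {i}, column 'dispersion_value': must be >= 0")
        records.append(rec)
    return PKDatabase(records=records, schema_version=schema_version)


def write_pk_database(db: PKDatabase, path: str | Path) -> None:
    """Write a database back to the canonical CSV layout (inverse of read)."""
    rows = []
    for rec in db.records:
        rows.append(
            {
                "study_id": rec.study_id,
                "substrate_id": rec.substrate_id,
                "isoform_ids": ";".join(rec.isoform_ids),
                "route": rec.route.value,
                "parameter": rec.parameter.value,
                "n_subjects": rec.n_subjects,
                "dose_value": rec.dose_value,
                "dose_basis": rec.dose_basis.value,
                "body_weight_kg": "" if rec.body_weight_kg is None else rec.body_weight_kg,
                "bsa_m2": "" if rec.bsa_m2 is None else rec.bsa_m2,
                "geography": rec.geography,
                "health_status": rec.health_status.value,
                "regimen": rec.regimen.value,
                "central_kind": rec.central_kind.value,
                "central_value": rec.central_value,
                "dispersion_kind": rec.dispersion_kind.value,
                "dispersion_value": rec.dispersion_value,
                "value_units": rec.value_units,
            }
        )
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def validate_records(
    db: PKDatabase,
    bsa_substrates: frozenset[str] = BSA_NORMALISED_SUBSTRATES,
) -> list[Violation]:
    """Check every record's invariants; return a report (never raises).

    Checks positivity constraints, GSD >= 1, the body-surface-area dose
    convention, and uniqueness of the study x substrate x route x parameter
    key (duplicates indicate an upstream extraction error, and are reported
    rather than silently deduplicated).
    """
    violations: list[Violation] = []
    seen: dict[tuple, int] = {}
    for i, rec in enumerate(db.records):
        if rec.n_subjects < 1:
            violations.append(Violation(i, rec.study_id, "n_subjects", "must be >= 1"))
        if rec.central_value <= 0:
            violations.append(Violation(i, rec.study_id, "central_value", "must be > 0"))
        if rec.dose_value <= 0:
            violations.append(Violation(i, rec.study_id, "dose_value", "must be > 0"))
        if rec.dispersion_value < 0:
            violations.append(Violation(i, rec.study_id, "dispersion_value", "must be >= 0"))
        if rec.dispersion_kind is DispersionKind.GSD and rec.dispersion_value < 1:
            violations.append(Violation(i, rec.study_id, "dispersion_value", "GSD >= 1"))
        if rec.body_weight_kg is not None and rec.body_weight_kg <= 0:
            violations.append(Violation(i, rec.study_id, "body_weight_kg", "must be > 0"))
        if rec.bsa_m2 is not None and rec.bsa_m2 <= 0:
            violations.append(Violation(i, rec.study_id, "bsa_m2", "must be > 0"))
        if rec.dose_basis is DoseBasis.MG_PER_M2 and rec.substrate_id not in bsa_substrates:
            violations.append(
                Violation(
                    i,
                    rec.study_id,
                    "dose_basis",
                    "mg_per_m2 allowed only for BSA-normalised substrates",
                )
            )
        if rec.key in seen:
            violations.append(
                Violation(
                    i,
                    rec.study_id,
                    "study_id",
                    f"duplicate study/substrate/route/parameter key (first at record {seen[rec.key]})",
                )
            )
        else:
            seen[rec.key] = i
    return violations


def select_analysis_set(
    db: PKDatabase,
    substrate: str,
    route: Route,
    parameter: Parameter,
    include_patients: bool = False,
    include_repeated: bool = False,
) -> PKDatabase:
    """Filter the database down to one substrate x route x parameter analysis set.

    Repeated-dosing records are excluded unless ``include_repeated`` is set
    (the ethinylestradiol 21-day contraceptive regimen is the one case where
    a caller legitimately sets it).  Patient records are excluded unless
    ``include_patients`` is set (needed for SN38, where only patient data
    exist, and deferiprone).
    """
    route = Route(route)
    parameter = Parameter(parameter)
    kept = [
        rec
        for rec in db.records
        if rec.substrate_id == substrate
        and rec.route is route
        and rec.parameter is parameter
        and (include_repeated or rec.regimen is not Regimen.REPEATED_21D)
        and (include_patients or rec.health_status is not HealthStatus.PATIENT)
    ]
    return PKDatabase(records=kept, schema_version=db.schema_version)
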