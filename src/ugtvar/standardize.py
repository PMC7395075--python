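"""Standardisation of heterogeneous PK summaries to lognormal (lnGM, lnGSD, n).

Published pharmacokinetic summaries arrive in four dispersion flavours
(SD, SE, CV, GSD) around either an arithmetic or a geometric mean, with the
dose given in total mg, mg/kg body weight, or mg/m^2 body surface area.
PK values are treated as lognormal throughout; an arithmetic mean/SD pair is
converted to geometric statistics by moment matching:

    CV_N = SD / AM
    GM   = AM / sqrt(1 + CV_N^2)
    GSD  = exp( sqrt( ln(1 + CV_N^2) ) )

Doses are brought to a per-kg (or, for BSA-normalised substrates, per-m^2)
basis using the reported mean body weight when available and a continent
default otherwise; Cmax and AUC are then expressed per unit normalised dose.
Clearance is already weight-normalised and is only converted to the
canonical reporting unit (mL/min/kg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io import (
    BSA_NORMALISED_SUBSTRATES,
    CentralKind,
    DispersionKind,
    DoseBasis,
    Parameter,
    Route,
    StudySummaryRecord,
)

__all__ = [
    "NormalizedObservation",
    "NormalizationConfig",
    "WALPOLE_CONTINENT_BODY_WEIGHTS",
    "CANONICAL_UNITS",
    "sd_from_dispersion",
    "am_sd_to_gm_gsd",
    "gm_gsd_to_am_sd",
    "normalize_dose",
    "normalize_record",
]

#: Regional mean adult body masses (kg), Walpole et al. (2012, BMC Public
#: Health).  The analysis cites these as dose-normalisation defaults but the
#: values are configuration, not truth: override them via NormalizationConfig.
WALPOLE_CONTINENT_BODY_WEIGHTS: dict[str, float] = {
    "Africa": 60.7,
    "Asia": 57.7,
    "Europe": 70.8,
    "Latin America": 67.9,
    "North America": 80.7,
    "Oceania": 74.1,
    "World": 62.0,
}

#: Canonical reporting units per PK parameter (dose-normalised where relevant).
CANONICAL_UNITS: dict[Parameter, str] = {
    Parameter.CMAX: "ng/mL per mg/kg",
    Parameter.AUC: "ng*h/mL per mg/kg",
    Parameter.CLEARANCE: "mL/min/kg",
}

# Multiplicative factors taking a reported unit to the canonical one.
_UNIT_FACTORS: dict[Parameter, dict[str, float]] = {
    Parameter.CMAX: {
        "ng/mL": 1.0,
        "ug/mL": 1e3,
        "mg/L": 1e3,
        "ng/L": 1e-3,
    },
    Parameter.AUC: {
        "ng*h/mL": 1.0,
        "ug*h/mL": 1e3,
        "mg*h/L": 1e3,
        "ng*min/mL": 1.0 / 60.0,
    },
    Parameter.CLEARANCE: {
        "mL/min/kg": 1.0,
        "L/h/kg": 1000.0 / 60.0,
        "mL/h/kg": 1.0 / 60.0,
        "L/min/kg": 1000.0,
    },
}


@dataclass(frozen=True)
class NormalizedObservation:
    """A dose- and unit-normalised study summary on the log scale."""

    substrate_id: str
    route: Route
    parameter: Parameter
    n_subjects: int
    ln_gm: float
    ln_gsd: float
    source_study_id: str

    def __post_init__(self) -> None:
        if self.ln_gsd < 0:
            raise ValueError("ln_gsd must be >= 0")
        if not (math.isfinite(self.ln_gm) and math.isfinite(self.ln_gsd)):
            raise ValueError("normalized observation must be finite")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass
class NormalizationConfig:
    """Dose/body-size defaults used when a study does not report them."""

    continent_body_weights: dict[str, float] = field(
        default_factory=lambda: dict(WALPOLE_CONTINENT_BODY_WEIGHTS)
    )
    default_bsa_m2: float = 1.79
    bsa_substrates: frozenset[str] = BSA_NORMALISED_SUBSTRATES
    canonical_units: dict[Parameter, str] = field(
        default_factory=lambda: dict(CANONICAL_UNITS)
    )

    def __post_init__(self) -> None:
        if self.default_bsa_m2 <= 0:
            raise ValueError("default_bsa_m2 must be positive")
        for label, bw in self.continent_body_weights.items():
            if bw <= 0:
                raise ValueError(f"body weight for {label!r} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NormalizationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "continent_body_weights" in raw:
            kwargs["continent_body_weights"] = {
                str(k): float(v) for k, v in raw["continent_body_weights"].items()
            }
        if "default_bsa_m2" in raw:
            kwargs["default_bsa_m2"] = float(raw["default_bsa_m2"])
        if "bsa_substrates" in raw:
            kwargs["bsa_substrates"] = frozenset(raw["bsa_substrates"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "continent_body_weights": self.continent_body_weights,
            "default_bsa_m2": self.default_bsa_m2,
            "bsa_substrates": sorted(self.bsa_substrates),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def sd_from_dispersion(
    kind: DispersionKind, value: float, n: int, mean: float
) -> float:
    """Recover the sample SD from whichever dispersion statistic was reported.

    SE is converted via SD = SE * sqrt(n); a CV (as a fraction, never a
    percent) via SD = CV * AM.  GSD never passes through this path — it pairs
    with a geometric mean and needs no conversion.
    """
    kind = DispersionKind(kind)
    if value < 0:
        raise ValueError("dispersion value must be >= 0")
    if kind is DispersionKind.SD:
        return value
    if kind is DispersionKind.SE:
        if n < 2:
            raise ValueError("SE reported with n < 2 cannot be converted to SD")
        return value * math.sqrt(n)
    if kind is DispersionKind.CV_FRACTION:
        if mean <= 0:
            raise ValueError("CV conversion requires a positive mean")
        return value * mean
    raise ValueError("GSD does not convert to SD; use the geometric path directly")


def am_sd_to_gm_gsd(am: float, sd: float) -> tuple[float, float]:
    """Moment-match an arithmetic mean/SD to lognormal GM/GSD."""
    if am <= 0:
        raise ValueError("arithmetic mean must be positive")
    if sd < 0:
        raise ValueError("SD must be >= 0")
    cv2 = (sd / am) ** 2
    gm = am / math.sqrt(1.0 + cv2)
    gsd = math.exp(math.sqrt(math.log1p(cv2)))
    return gm, gsd


def gm_gsd_to_am_sd(gm: float, gsd: float) -> tuple[float, float]:
    """Exact inverse of :func:`am_sd_to_gm_gsd` under lognormal moment matching."""
    if gm <= 0:
        raise ValueError("geometric mean must be positive")
    if gsd < 1:
        raise ValueError("GSD must be >= 1")
    cv = math.sqrt(math.expm1(math.log(gsd) ** 2))
    am = gm * math.sqrt(1.0 + cv * cv)
    return am, cv * am


def normalize_dose(record: StudySummaryRecord, config: NormalizationConfig) -> float:
    """Express the administered dose per kg body weight (or per m^2 BSA).

    Doses already on a per-kg or per-m^2 basis pass through.  Total-mg doses
    for BSA-normalised substrates divide by the reported body surface area,
    falling back to the configured default (1.79 m^2); all other total-mg
    doses divide by the reported mean body weight, falling back to the
    continent default for the record's geography.
    """
    if record.dose_basis in (DoseBasis.MG_PER_KG, DoseBasis.MG_PER_M2):
        return record.dose_value
    # total mg
    if record.substrate_id in config.bsa_substrates:
        bsa = record.bsa_m2 if record.bsa_m2 is not None else config.default_bsa_m2
        return record.dose_value / bsa
    if record.body_weight_kg is not None:
        return record.dose_value / record.body_weight_kg
    try:
        bw = config.continent_body_weights[record.geography]
    except KeyError:
        raise ValueError(
            f"study {record.study_id!r}: total-mg dose with no body weight and no "
            f"continent default for geography {record.geography!r}"
        ) from None
    return record.dose_value / bw


def _unit_factor(parameter: Parameter, units: str) -> float:
    table = _UNIT_FACTORS[parameter]
    # tolerate the common typographic variants of the multiplication dot
    key = units.replace("·", "*").replace(".h", "*h").replace("µ", "u").strip()
    try:
        return table[key]
    except KeyError:
        known = ", ".join(sorted(table))
        raise ValueError(
            f"unknown unit {units!r} for parameter {parameter.value} (known: {known})"
        ) from None


def normalize_record(
    record: StudySummaryRecord, config: NormalizationConfig
) -> NormalizedObservation:
    """Convert one reported study summary to a canonical (lnGM, lnGSD, n) triple."""
    if record.central_kind is CentralKind.GM:
        if record.dispersion_kind is not DispersionKind.GSD:
            raise ValueError(
                f"study {record.study_id!r}: geometric mean must pair with GSD"
            )
        if record.dispersion_value < 1:
            raise ValueError(f"study {record.study_id!r}: GSD must be >= 1")
        gm, gsd = record.central_value, record.dispersion_value
    else:
        if record.dispersion_kind is DispersionKind.GSD:
            raise ValueError(
                f"study {record.study_id!r}: arithmetic mean cannot pair with GSD"
            )
        sd = sd_from_dispersion(
            record.dispersion_kind,
            record.dispersion_value,
            record.n_subjects,
            record.central_value,
        )
        gm, gsd = am_sd_to_gm_gsd(record.central_value, sd)

    gm *= _unit_factor(record.parameter, record.value_units)
    if record.parameter in (Parameter.CMAX, Parameter.AUC):
        gm /= normalize_dose(record, config)
    # clearance: unit conversion above is the whole normalisation

    return NormalizedObservation(
        substrate_id=record.substrate_id,
        route=record.route,
        parameter=record.parameter,
        n_subjects=record.n_subjects,
        ln_gm=math.log(gm),
        ln_gsd=math.log(gsd),
        source_study_id=record.study_id,
    )
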