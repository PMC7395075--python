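"""Synthetic multi-study PK databases with known ground truth.

The generator emulates the statistical structure of a literature-derived PK
summary database: lognormal individual values, study-level random effects,
several substrates per isoform, study sizes in the published range (~6-80),
heterogeneous reporting (AM/SD, AM/SE, AM/CV or GM/GSD), doses given as
total mg with the mean body weight sometimes unreported.  Ground truth
(mu_j, sigma_ind_j, sigma_study_j per substrate) travels alongside the
generated database so recovery tests never re-derive it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import (
    CentralKind,
    DispersionKind,
    DoseBasis,
    HealthStatus,
    Parameter,
    PKDatabase,
    Regimen,
    Route,
    StudySummaryRecord,
)

__all__ = [
    "SubstrateTruth",
    "DoseScheme",
    "SyntheticScenario",
    "simulate_individuals",
    "simulate_study_summaries",
    "make_isoform_preset",
    "PRESET_NAMES",
    "write_truth",
]

_REPORT_MODES = ("AM_SD", "AM_SE", "AM_CV", "GM_GSD")


@dataclass(frozen=True)
class SubstrateTruth:
    """Generative parameters for one substrate (canonical log scale)."""

    substrate_id: str
    mu: float
    sigma_ind: float
    sigma_study: float
    n_studies: int


@dataclass(frozen=True)
class DoseScheme:
    """How doses and body sizes appear in the generated records."""

    dose_value: float
    dose_basis: DoseBasis
    body_weight_mean: float = 70.8
    body_weight_sd: float = 10.0
    fraction_missing_bw: float = 0.1
    geography: str = "Europe"


@dataclass
class SyntheticScenario:
    """Ground-truth description of a simulated multi-study database."""

    substrates: list[SubstrateTruth]
    subjects_per_study: tuple[int, int]
    dose_scheme: DoseScheme
    reporting_mix: dict[str, float]
    parameter: Parameter
    route: Route
    isoform_id: str = "UGTx"
    seed: int = 0

    def validate(self) -> None:
        if not self.substrates:
            raise ValueError("scenario needs at least one substrate")
        for s in self.substrates:
            if s.sigma_ind <= 0 or s.sigma_study <= 0:
                raise ValueError(f"{s.substrate_id}: sigmas must be > 0")
            if s.n_studies < 1:
                raise ValueError(f"{s.substrate_id}: n_studies must be >= 1")
        lo, hi = self.subjects_per_study
        if not (1 <= lo <= hi):
            raise ValueError("subjects_per_study range must be nonempty and >= 1")
        if set(self.reporting_mix) - set(_REPORT_MODES):
            raise ValueError(f"reporting modes must be among {_REPORT_MODES}")
        if abs(sum(self.reporting_mix.values()) - 1.0) > 1e-9:
            raise ValueError("reporting_mix probabilities must sum to 1")
        if not 0.0 <= self.dose_scheme.fraction_missing_bw <= 1.0:
            raise ValueError("fraction_missing_bw must be in [0, 1]")

    def truth(self) -> dict:
        """JSON-serialisable ground truth (sidecar for recovery tests)."""
        return {
            "seed": self.seed,
            "parameter": self.parameter.value,
            "route": self.route.value,
            "isoform_id": self.isoform_id,
            "substrates": [
                {
                    "substrate_id": s.substrate_id,
                    "mu": s.mu,
                    "sigma_ind": s.sigma_ind,
                    "sigma_study": s.sigma_study,
                    "cv_ind": math.sqrt(math.expm1(s.sigma_ind**2)),
                    "n_studies": s.n_studies,
                }
                for s in self.substrates
            ],
        }


def simulate_individuals(
    scenario: SyntheticScenario,
    substrate: int,
    study: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Individual PK values (canonical units) for one study.

    Draws the study size from the scenario's range, a study effect
    m ~ Normal(mu_j, sigma_study_j^2), then individual log values around it;
    returns the exponentiated vector.
    """
    scenario.validate()
    truth = scenario.substrates[substrate]
    lo, hi = scenario.subjects_per_study
    n = int(rng.integers(lo, hi + 1))
    m = rng.normal(truth.mu, truth.sigma_study)
    return np.exp(rng.normal(m, truth.sigma_ind, size=n))


def _clearance_units(rng: np.random.Generator) -> tuple[str, float]:
    # published clearances mix mL/min/kg and L/h/kg; exercise both.
    # The factor converts a canonical mL/min/kg value into the reported unit.
    if rng.random() < 0.3:
        return "L/h/kg", 60.0 / 1000.0
    return "mL/min/kg", 1.0


def simulate_study_summaries(
    scenario: SyntheticScenario,
) -> tuple[PKDatabase, dict]:
    """Simulate every study, summarise per the drawn reporting mode.

    Returns the database (exactly the CSV schema of :mod:`ugtvar.io`) and
    the scenario's ground-truth dictionary.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    modes = list(scenario.reporting_mix)
    probs = np.array([scenario.reporting_mix[m] for m in modes])
    scheme = scenario.dose_scheme
    records: list[StudySummaryRecord] = []
    for j, truth in enumerate(scenario.substrates):
        for i in range(truth.n_studies):
            values = simulate_individuals(scenario, j, i, rng)
            n = values.size
            mode = modes[int(rng.choice(len(modes), p=probs))]

            # dose and body size bookkeeping
            bw = float(np.clip(rng.normal(scheme.body_weight_mean, scheme.body_weight_sd), 40.0, None))
            bw_missing = rng.random() < scheme.fraction_missing_bw
            if scheme.dose_basis is DoseBasis.TOTAL_MG:
                dose_per_kg = scheme.dose_value / bw
            else:
                dose_per_kg = scheme.dose_value

            if scenario.parameter is Parameter.CLEARANCE:
                units, factor = _clearance_units(rng)
                reported = values * factor
            else:
                units = "ng*h/mL" if scenario.parameter is Parameter.AUC else "ng/mL"
                reported = values * dose_per_kg

            if mode == "GM_GSD":
                logs = np.log(reported)
                central_kind = CentralKind.GM
                central = float(np.exp(np.mean(logs)))
                disp_kind = DispersionKind.GSD
                disp = float(np.exp(np.std(logs, ddof=1))) if n >= 2 else 1.0
            else:
                central_kind = CentralKind.AM
                central = float(np.mean(reported))
                sd = float(np.std(reported, ddof=1)) if n >= 2 else 0.0
                if mode == "AM_SD":
                    disp_kind, disp = DispersionKind.SD, sd
                elif mode == "AM_SE":
                    disp_kind, disp = DispersionKind.SE, sd / math.sqrt(n)
                else:
                    disp_kind, disp = DispersionKind.CV_FRACTION, (sd / central if central > 0 else 0.0)

            records.append(
                StudySummaryRecord(
                    study_id=f"{truth.substrate_id}_study{i + 1:03d}",
                    substrate_id=truth.substrate_id,
                    isoform_ids=(scenario.isoform_id,),
                    route=scenario.route,
                    parameter=scenario.parameter,
                    n_subjects=n,
                    dose_value=scheme.dose_value,
                    dose_basis=scheme.dose_basis,
                    body_weight_kg=None if bw_missing else bw,
                    bsa_m2=None,
                    geography=scheme.geography,
                    health_status=HealthStatus.HEALTHY,
                    regimen=Regimen.SINGLE_DOSE,
                    central_kind=central_kind,
                    central_value=central,
                    dispersion_kind=disp_kind,
                    dispersion_value=disp,
                    value_units=units,
                )
            )
    return PKDatabase(records=records), scenario.truth()


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)


def _cv_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


_DEFAULT_MIX = {"AM_SD": 0.6, "AM_SE": 0.15, "AM_CV": 0.1, "GM_GSD": 0.15}


def _preset_default(seed: int) -> SyntheticScenario:
    # the reference recovery scenario: two substrates, 12 studies each,
    # 20 subjects per study, interindividual CV 0.5, interstudy SD 0.2
    return SyntheticScenario(
        substrates=[
            SubstrateTruth("substrate_A", math.log(300.0), _cv_sigma(0.5), 0.2, 12),
            SubstrateTruth("substrate_B", math.log(100.0), _cv_sigma(0.5), 0.2, 12),
        ],
        subjects_per_study=(20, 20),
        dose_scheme=DoseScheme(300.0, DoseBasis.TOTAL_MG),
        reporting_mix=dict(_DEFAULT_MIX),
        parameter=Parameter.AUC,
        route=Route.ORAL,
        isoform_id="UGTx",
        seed=seed,
    )


def _preset_ugt2b7_oral_auc(seed: int) -> SyntheticScenario:
    # mimics the published UGT2B7 oral AUC table: codeine (18 studies) and
    # zidovudine (12 studies), interindividual CVs around 0.28-0.29
    return SyntheticScenario(
        substrates=[
            SubstrateTruth("codeine", math.log(295.0), _cv_sigma(0.29), 0.15, 18),
            SubstrateTruth("zidovudine", math.log(477.0), _cv_sigma(0.28), 0.15, 12),
        ],
        subjects_per_study=(10, 20),
        dose_scheme=DoseScheme(100.0, DoseBasis.TOTAL_MG),
        reporting_mix=dict(_DEFAULT_MIX),
        parameter=Parameter.AUC,
        route=Route.ORAL,
        isoform_id="UGT2B7",
        seed=seed,
    )


def _preset_ugt1a6_oral_clearance(seed: int) -> SyntheticScenario:
    # mimics the published UGT1A6 oral clearance table: deferiprone,
    # 9 studies, interindividual CV around 0.40, GM about 1.9 mL/min/kg
    return SyntheticScenario(
        substrates=[
            SubstrateTruth("deferiprone", math.log(1.9), _cv_sigma(0.40), 0.15, 9),
        ],
        subjects_per_study=(6, 14),
        dose_scheme=DoseScheme(25.0, DoseBasis.MG_PER_KG),
        reporting_mix=dict(_DEFAULT_MIX),
        parameter=Parameter.CLEARANCE,
        route=Route.ORAL,
        isoform_id="UGT1A6",
        seed=seed,
    )


_PRESETS = {
    "default": _preset_default,
    "ugt2b7_oral_auc": _preset_ugt2b7_oral_auc,
    "ugt1a6_oral_clearance": _preset_ugt1a6_oral_clearance,
}

PRESET_NAMES: tuple[str, ...] = tuple(sorted(_PRESETS))


def make_isoform_preset(name: str, seed: int = 0) -> SyntheticScenario:
    """A shipped scenario mimicking a published isoform table's structure."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
        ) from None
    scenario = factory(seed)
    scenario.validate()
    return scenario
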