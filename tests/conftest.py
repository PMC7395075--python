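import numpy as np
import pytest

from ugtvar.io import (
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
from ugtvar.model import McmcConfig, PriorConfig, build_model_spec, run_mcmc
from ugtvar.simulate import make_isoform_preset, simulate_study_summaries
from ugtvar.standardize import NormalizationConfig, normalize_record


def make_record(**overrides) -> StudySummaryRecord:
    """A valid oral AUC record; override any field."""
    base = dict(
        study_id="study001",
        substrate_id="zidovudine",
        isoform_ids=("UGT2B7",),
        route=Route.ORAL,
        parameter=Parameter.AUC,
        n_subjects=12,
        dose_value=300.0,
        dose_basis=DoseBasis.TOTAL_MG,
        body_weight_kg=70.0,
        bsa_m2=None,
        geography="Europe",
        health_status=HealthStatus.HEALTHY,
        regimen=Regimen.SINGLE_DOSE,
        central_kind=CentralKind.AM,
        central_value=2000.0,
        dispersion_kind=DispersionKind.SD,
        dispersion_value=600.0,
        value_units="ng*h/mL",
    )
    base.update(overrides)
    return StudySummaryRecord(**base)


@pytest.fixture
def norm_config() -> NormalizationConfig:
    return NormalizationConfig()


@pytest.fixture
def two_record_db() -> PKDatabase:
    return PKDatabase(
        records=[
            make_record(),
            make_record(
                study_id="study002",
                substrate_id="telmisartan",
                isoform_ids=("UGT1A3",),
                route=Route.IV,
                parameter=Parameter.CLEARANCE,
                dose_basis=DoseBasis.MG_PER_KG,
                dose_value=1.0,
                central_value=12.0,
                dispersion_value=4.0,
                value_units="mL/min/kg",
            ),
        ]
    )


@pytest.fixture(scope="session")
def default_fit():
    """One pooled fit of the reference synthetic scenario, reused read-only."""
    scenario = make_isoform_preset("default", seed=11)
    db, truth = simulate_study_summaries(scenario)
    cfg = NormalizationConfig()
    observations = [normalize_record(r, cfg) for r in db]
    spec = build_model_spec(observations, PriorConfig())
    draws = run_mcmc(
        spec, McmcConfig(chains=2, warmup_draws=600, kept_draws=800, seed=5, min_ess=100)
    )
    return spec, draws, truth
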