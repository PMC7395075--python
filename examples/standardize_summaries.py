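"""Standardise heterogeneous published PK summaries to lognormal form.

Two studies report the same oral AUC endpoint differently: one as an
arithmetic mean with SD and a total-mg dose, the other as a geometric mean
with GSD and a per-kg dose.  Both become comparable (lnGM, lnGSD, n)
observations per unit dose.
"""

import math

from ugtvar.io import (
    CentralKind,
    DispersionKind,
    DoseBasis,
    HealthStatus,
    Parameter,
    Regimen,
    Route,
    StudySummaryRecord,
)
from ugtvar.standardize import NormalizationConfig, normalize_record

config = NormalizationConfig()

am_study = StudySummaryRecord(
    study_id="study_A", substrate_id="zidovudine", isoform_ids=("UGT2B7",),
    route=Route.ORAL, parameter=Parameter.AUC, n_subjects=12,
    dose_value=300.0, dose_basis=DoseBasis.TOTAL_MG, body_weight_kg=70.0,
    bsa_m2=None, geography="Europe", health_status=HealthStatus.HEALTHY,
    regimen=Regimen.SINGLE_DOSE, central_kind=CentralKind.AM,
    central_value=2000.0, dispersion_kind=DispersionKind.SD,
    dispersion_value=600.0, value_units="ng*h/mL",
)
gm_study = StudySummaryRecord(
    study_id="study_B", substrate_id="zidovudine", isoform_ids=("UGT2B7",),
    route=Route.ORAL, parameter=Parameter.AUC, n_subjects=8,
    dose_value=4.0, dose_basis=DoseBasis.MG_PER_KG, body_weight_kg=None,
    bsa_m2=None, geography="Europe", health_status=HealthStatus.HEALTHY,
    regimen=Regimen.SINGLE_DOSE, central_kind=CentralKind.GM,
    central_value=450.0, dispersion_kind=DispersionKind.GSD,
    dispersion_value=1.5, value_units="ng*h/mL",
)

for rec in (am_study, gm_study):
    obs = normalize_record(rec, config)
    print(
        f"{rec.study_id}: GM = {math.exp(obs.ln_gm):7.1f} ng*h/mL per mg/kg, "
        f"GSD = {math.exp(obs.ln_gsd):5.3f}, n = {obs.n_subjects}"
    )

# Both studies now share units and dose basis; the GSD is the study's
# observed interindividual spread and feeds the dispersion likelihood.
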