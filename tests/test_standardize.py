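import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ugtvar.io import CentralKind, DispersionKind, DoseBasis
from ugtvar.standardize import (
    NormalizationConfig,
    am_sd_to_gm_gsd,
    gm_gsd_to_am_sd,
    normalize_dose,
    normalize_record,
    sd_from_dispersion,
)

from conftest import make_record


@pytest.mark.parametrize(
    "kind, value, n, mean, expected",
    [
        (DispersionKind.SE, 2.0, 25, 100.0, 10.0),
        (DispersionKind.CV_FRACTION, 0.3, 10, 50.0, 15.0),
        (DispersionKind.SD, 7.0, 10, 100.0, 7.0),
    ],
)
def test_sd_from_dispersion(kind, value, n, mean, expected):
    assert sd_from_dispersion(kind, value, n, mean) == pytest.approx(expected)


def test_sd_from_dispersion_rejects_gsd_and_tiny_n():
    with pytest.raises(ValueError, match="GSD"):
        sd_from_dispersion(DispersionKind.GSD, 1.5, 10, 100.0)
    with pytest.raises(ValueError, match="n < 2"):
        sd_from_dispersion(DispersionKind.SE, 1.0, 1, 100.0)


@pytest.mark.parametrize(
    "am, sd, gm, gsd",
    [
        (100.0, 0.0, 100.0, 1.0),
        (100.0, 50.0, 89.44272, 1.60381),
        (10.0, 10.0, 7.07107, 2.29918),
    ],
)
def test_am_sd_to_gm_gsd_reference_values(am, sd, gm, gsd):
    got_gm, got_gsd = am_sd_to_gm_gsd(am, sd)
    assert got_gm == pytest.approx(gm, abs=5e-5)
    assert got_gsd == pytest.approx(gsd, abs=5e-5)


def test_moment_matching_agrees_with_simulation():
    # a large lognormal sample's AM/SD must map back near its GM/GSD
    rng = np.random.default_rng(42)
    ln = rng.normal(math.log(50.0), 0.5, size=2_000_000)
    x = np.exp(ln)
    gm, gsd = am_sd_to_gm_gsd(float(np.mean(x)), float(np.std(x, ddof=1)))
    assert gm == pytest.approx(math.exp(np.mean(ln)), rel=5e-3)
    assert math.log(gsd) == pytest.approx(float(np.std(ln, ddof=1)), rel=5e-3)


@given(cv=st.floats(min_value=0.0, max_value=5.0), am=st.floats(min_value=1e-3, max_value=1e6))
@settings(max_examples=200, deadline=None)
def test_conversions_are_mutual_inverses(cv, am):
    sd = cv * am
    gm, gsd = am_sd_to_gm_gsd(am, sd)
    am2, sd2 = gm_gsd_to_am_sd(gm, gsd)
    assert am2 == pytest.approx(am, rel=1e-12, abs=1e-12)
    assert sd2 == pytest.approx(sd, rel=1e-12, abs=1e-9 * am)
    # GM never exceeds AM; equality only without dispersion
    assert gm <= am * (1 + 1e-15)
    if cv > 1e-6:
        assert gm < am


def test_gsd_increases_with_sd():
    gsds = [am_sd_to_gm_gsd(100.0, sd)[1] for sd in (0.0, 10.0, 50.0, 200.0)]
    assert gsds == sorted(gsds)
    assert gsds[0] == pytest.approx(1.0)


def test_gm_gsd_to_am_sd_rejects_gsd_below_one():
    with pytest.raises(ValueError):
        gm_gsd_to_am_sd(10.0, 0.9)


class TestNormalizeDose:
    def test_reported_body_weight(self, norm_config):
        rec = make_record(dose_value=100.0, body_weight_kg=50.0)
        assert normalize_dose(rec, norm_config) == pytest.approx(2.0)

    def test_continent_default_when_weight_missing(self):
        cfg = NormalizationConfig(continent_body_weights={"Europe": 70.0})
        rec = make_record(dose_value=140.0, body_weight_kg=None, geography="Europe")
        assert normalize_dose(rec, cfg) == pytest.approx(2.0)

    def test_bsa_substrate_uses_default_bsa(self, norm_config):
        rec = make_record(
            substrate_id="SN38",
            dose_value=626.5,
            dose_basis=DoseBasis.TOTAL_MG,
            body_weight_kg=None,
            bsa_m2=None,
        )
        assert normalize_dose(rec, norm_config) == pytest.approx(626.5 / 1.79)

    def test_bsa_wins_over_body_weight(self, norm_config):
        rec = make_record(
            substrate_id="SN38", dose_value=360.0, body_weight_kg=70.0, bsa_m2=1.8
        )
        assert normalize_dose(rec, norm_config) == pytest.approx(200.0)

    def test_unknown_geography_is_an_error(self):
        cfg = NormalizationConfig(continent_body_weights={})
        rec = make_record(body_weight_kg=None, geography="Atlantis")
        with pytest.raises(ValueError, match="Atlantis"):
            normalize_dose(rec, cfg)

    def test_per_kg_dose_passes_through(self, norm_config):
        rec = make_record(dose_basis=DoseBasis.MG_PER_KG, dose_value=3.5)
        assert normalize_dose(rec, norm_config) == pytest.approx(3.5)


class TestNormalizeRecord:
    def test_geometric_identity_path(self, norm_config):
        rec = make_record(
            central_kind=CentralKind.GM,
            central_value=250.0,
            dispersion_kind=DispersionKind.GSD,
            dispersion_value=1.8,
            dose_basis=DoseBasis.MG_PER_KG,
            dose_value=1.0,
        )
        obs = normalize_record(rec, norm_config)
        assert obs.ln_gm == pytest.approx(math.log(250.0))
        assert obs.ln_gsd == pytest.approx(math.log(1.8))

    def test_arithmetic_path_composes_conversions(self, norm_config):
        rec = make_record(
            central_value=100.0,
            dispersion_value=50.0,
            dose_basis=DoseBasis.MG_PER_KG,
            dose_value=2.0,
        )
        obs = normalize_record(rec, norm_config)
        assert obs.ln_gm == pytest.approx(math.log(89.4427 / 2.0), abs=1e-5)
        assert obs.ln_gsd == pytest.approx(math.log(1.6038), abs=1e-4)

    def test_clearance_unit_conversion(self, norm_config):
        rec = make_record(
            parameter="clearance",
            central_value=2.0,
            dispersion_value=0.0,
            value_units="L/h/kg",
        )
        obs = normalize_record(rec, norm_config)
        assert math.exp(obs.ln_gm) == pytest.approx(2000.0 / 60.0)

    def test_dose_unit_invariance(self, norm_config):
        # the same physical dose expressed two ways gives the same observation
        as_total = make_record(dose_value=140.0, body_weight_kg=70.0)
        as_per_kg = make_record(dose_basis=DoseBasis.MG_PER_KG, dose_value=2.0)
        o1 = normalize_record(as_total, norm_config)
        o2 = normalize_record(as_per_kg, norm_config)
        assert o1.ln_gm == pytest.approx(o2.ln_gm, rel=1e-12)
        assert o1.ln_gsd == pytest.approx(o2.ln_gsd, rel=1e-12)

    def test_mismatched_central_dispersion_pairs_rejected(self, norm_config):
        rec = make_record(dispersion_kind=DispersionKind.GSD, dispersion_value=1.5)
        with pytest.raises(ValueError, match="GSD"):
            normalize_record(rec, norm_config)

    def test_unknown_units_rejected(self, norm_config):
        rec = make_record(value_units="furlongs")
        with pytest.raises(ValueError, match="furlongs"):
            normalize_record(rec, norm_config)
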