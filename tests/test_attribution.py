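"""Factorial experiments, ledger decomposition, PFT composites, forcing bias."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from optigpp import attribution as at
from optigpp import constants as cn
from optigpp import photo_core as pc
from optigpp import traits as tr


def small_forcing(site="S", years=(2015, 2015)):
    rows = []
    for year in range(years[0], years[1] + 1):
        for month, (tc, vpd, ppfd) in enumerate(
                [(25.0, 800.0, 1000.0), (26.0, 1200.0, 1100.0)], start=1):
            rows.append(dict(site=site, year=year, month=month, tc=tc, vpd=vpd,
                             co2=400.0, patm=101325.0, ppfd=ppfd))
    return pd.DataFrame(rows)


def make_inputs(fapar_field=0.9, fapar_sat=0.6, cwm=None, **kw):
    f = small_forcing()
    return at.SiteInputs(
        site="S", forcing_field=f, forcing_product=f.copy(),
        fapar_field=pd.Series(fapar_field, index=range(1, 13)),
        fapar_satellite=pd.Series(fapar_sat, index=range(1, 13)),
        cwm=cwm, **kw,
    )


def closed_form_lue(tc, vpd, co2=400.0, patm=101325.0, phi0=0.05, beta=146.0,
                    cstar=0.41):
    """Spreadsheet-style independent recomputation of the optimality LUE."""
    R = 8.3145
    arr = lambda r, d: r * math.exp(d / R * (1 / 298.15 - 1 / (tc + 273.15)))
    g = arr(4.332, 37830.0) * patm / 101325.0
    kc = arr(39.97, 79430.0)
    ko = arr(27480.0, 36380.0)
    kmm = kc * (1 + patm * 0.2095 / ko)
    eta = math.exp(247.8 / (tc + 273.15 - 140) - 247.8 / (298.15 - 140))
    ca = co2 * 1e-6 * patm
    xi = math.sqrt(beta * (kmm + g) / (1.6 * eta))
    chi = g / ca + (1 - g / ca) * xi / (xi + math.sqrt(vpd))
    ci = chi * ca
    mj = (ci - g) / (ci + 2 * g)
    mp = mj * math.sqrt(1 - (cstar / mj) ** (2 / 3)) if mj > cstar else 0.0
    return phi0 * mp * 12.0107


class TestExperimentEngine:
    def test_identical_bindings_identical_gpp(self):
        inputs = make_inputs()
        a = at.ExperimentSpec("x", "optimality", "field", "field")
        b = at.ExperimentSpec("y", "optimality", "field", "field")
        assert at.run_experiment(a, inputs) == at.run_experiment(b, inputs)

    def test_pf_equals_p_when_satellite_matches_field(self):
        inputs = make_inputs(fapar_field=0.85, fapar_sat=0.85)
        assert at.run_experiment("Pmodel_Pf", inputs) == at.run_experiment(
            "Pmodel_P", inputs)

    def test_annual_gpp_matches_chained_arithmetic_oracle(self):
        """Pmodel_Pf annual GPP against an independent closed-form recomputation."""
        inputs = make_inputs(fapar_field=0.9)
        expect = sum(0.9 * closed_form_lue(tc, vpd) * ppfd
                     for tc, vpd, ppfd in
                     [(25.0, 800.0, 1000.0), (26.0, 1200.0, 1100.0)]) * 0.01
        assert at.run_experiment("Pmodel_Pf", inputs) == pytest.approx(
            expect, rel=1e-10)

    def test_missing_traits_binding_raises_named_error(self):
        inputs = make_inputs(cwm=None)
        with pytest.raises(ValueError, match="traits"):
            at.run_experiment("Pmodel_PfL", inputs)

    def test_invalid_source_names_rejected(self):
        with pytest.raises(ValueError):
            at.ExperimentSpec("x", "magic", "field", "field")

    def test_controlled_difference_fapar_only(self):
        """Swapping only the fAPAR binding moves only the fAPAR term."""
        v, j = 80.0, 140.0
        cwm = tr.TraitRecord("cwm", v, j, v, j, 0.015 * v, 0.8)
        inputs = make_inputs(fapar_field=0.9, fapar_sat=0.6, cwm=cwm,
                             growth_tc=25.5)
        gpps = at.run_all_experiments(inputs)
        led = at.decompose(40.0, gpps["Pmodel_PfL"], gpps["Pmodel_Pf"],
                           gpps["Pmodel_P"], gpps["product"])
        # Pf and P differ only in fAPAR: the ratio of GPPs equals the ratio
        # of (constant) fAPAR climatologies
        assert gpps["Pmodel_P"] == pytest.approx(
            gpps["Pmodel_Pf"] * 0.6 / 0.9, rel=1e-12)
        # and with satellite == field fAPAR, the fapar term collapses to 0
        inputs_eq = make_inputs(fapar_field=0.9, fapar_sat=0.9, cwm=cwm,
                                growth_tc=25.5)
        gpps_eq = at.run_all_experiments(inputs_eq)
        led_eq = at.decompose(40.0, gpps_eq["Pmodel_PfL"], gpps_eq["Pmodel_Pf"],
                              gpps_eq["Pmodel_P"], gpps_eq["product"])
        assert led_eq.fapar_term == pytest.approx(0.0, abs=1e-12)
        assert led_eq.traits_term == pytest.approx(led.traits_term *
                                                   1.0, rel=1e-9)


class TestLookupLue:
    def test_below_tmin_ramp_gives_zero(self):
        biome = at.BiomeLookupParams()
        assert at.lookup_lue(-9.0, 500.0, biome) == 0.0

    def test_low_vpd_gives_unit_vpd_scalar(self):
        biome = at.BiomeLookupParams(vpd_daytime_factor=1.0)
        assert at.lookup_lue(25.0, 500.0, biome) == pytest.approx(
            biome.epsilon_max, rel=1e-12)

    def test_mid_ramp_linear_interpolation(self):
        biome = at.BiomeLookupParams(vpd_daytime_factor=1.0)
        # vpd = 1950 Pa is halfway between 800 and 3100
        assert at.lookup_lue(25.0, 1950.0, biome) == pytest.approx(
            biome.epsilon_max * 0.5, rel=1e-12)

    def test_malformed_ramp_bounds_rejected(self):
        with pytest.raises(ValueError):
            at.BiomeLookupParams(vpd_min=3100.0, vpd_max=800.0)


class TestDecompose:
    def test_worked_quintuple(self):
        led = at.decompose(40.0, 32.0, 28.0, 20.0, 15.0)
        assert (led.unresolved, led.traits_term, led.fapar_term,
                led.optimisation_term) == (8.0, 4.0, 8.0, 5.0)
        assert led.total == 25.0

    def test_all_equal_gives_zero_ledger(self):
        led = at.decompose(30.0, 30.0, 30.0, 30.0, 30.0)
        assert led.total == led.unresolved == led.traits_term == 0.0

    def test_percent_of_biometric(self):
        led = at.decompose(40.0, 32.0, 28.0, 20.0, 15.0)
        pct = led.percent_of_biometric()
        assert pct["unresolved"] == pytest.approx(20.0)
        assert pct["total"] == pytest.approx(62.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=5, max_size=5))
    def test_telescoping_identity(self, vals):
        led = at.decompose(*vals)
        assert (led.unresolved + led.traits_term + led.fapar_term +
                led.optimisation_term) == pytest.approx(led.total, abs=1e-9)


class TestComposite:
    def test_single_pft(self):
        df = pd.DataFrame({"pft": ["f"], "fraction": [1.0], "gpp": [22.0],
                           "is_forest": [True]})
        assert at.composite_gpp(df) == 22.0
        assert at.forest_only_gpp(df) == 22.0

    def test_forest_grass_split(self):
        df = pd.DataFrame({"pft": ["forest", "grass"], "fraction": [0.5, 0.5],
                           "gpp": [20.0, 10.0], "is_forest": [True, False]})
        assert at.composite_gpp(df) == pytest.approx(15.0)
        assert at.forest_only_gpp(df) == pytest.approx(20.0)

    def test_three_pft_hand_table(self):
        # 0.4*24 + 0.3*18 + 0.2*8 = 16.6; forest-only (0.4*24+0.3*18)/0.7 = 21.43
        df = pd.DataFrame({
            "pft": ["ebf", "dbf", "c4"], "fraction": [0.4, 0.3, 0.2],
            "gpp": [24.0, 18.0, 8.0], "is_forest": [True, True, False]})
        assert at.composite_gpp(df) == pytest.approx(16.6)
        assert at.forest_only_gpp(df) == pytest.approx((0.4 * 24 + 0.3 * 18) / 0.7)

    def test_negative_fraction_rejected(self):
        df = pd.DataFrame({"pft": ["f"], "fraction": [-0.1], "gpp": [22.0],
                           "is_forest": [True]})
        with pytest.raises(ValueError):
            at.composite_gpp(df)


class TestForcingBias:
    def test_identical_series_zero_bias_and_rmse(self):
        f = small_forcing()
        rep = at.forcing_bias_report(f, f.copy())
        for var in ("tc", "vpd", "ppfd"):
            assert rep[var]["bias"] == 0.0 and rep[var]["rmse"] == 0.0

    def test_constant_offset_recovered_exactly(self):
        f = small_forcing()
        g = f.copy()
        g["tc"] = g["tc"] + 0.7
        rep = at.forcing_bias_report(f, g)
        assert rep["tc"]["bias"] == pytest.approx(0.7, rel=1e-12)
        assert rep["tc"]["rmse"] == pytest.approx(0.7, rel=1e-12)

    def test_misaligned_series_rejected(self):
        f = small_forcing()
        g = small_forcing(years=(2016, 2016))
        with pytest.raises(ValueError):
            at.forcing_bias_report(f, g)

    def test_gpp_sensitivity_sign_matches_ppfd_surplus(self):
        f = small_forcing()
        g = f.copy()
        g["ppfd"] = g["ppfd"] * 1.1
        inputs = make_inputs()
        rep = at.forcing_bias_report(f, g, inputs=inputs)
        # 10% more PPFD -> ~10% more GPP through the linear Eq. chain
        base = at.run_experiment("Pmodel_Pf", inputs)
        assert rep["ppfd"]["gpp_sensitivity"] == pytest.approx(0.1 * base, rel=0.02)

    def test_designed_product_offsets_recovered(self, dataset):
        for bundle in dataset.values():
            rep = at.forcing_bias_report(bundle.forcing_field,
                                         bundle.forcing_product)
            assert rep["tc"]["bias"] == pytest.approx(
                bundle.template.product_tc_offset, abs=1e-9)
            rel_ppfd = rep["ppfd"]["bias"] / bundle.forcing_field["ppfd"].mean()
            assert rel_ppfd == pytest.approx(
                bundle.template.product_ppfd_factor - 1.0, abs=5e-3)
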