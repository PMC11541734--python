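"""FvCB kinetics, optimal chi, limitation factors, LUE and coordination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optigpp import constants as c
from optigpp import photo_core as pc

from conftest import random_forcing


class TestArrhenius:
    def test_identity_at_reference_temperature(self):
        assert pc.arrhenius_scale(50.0, 65330.0, 25.0, 25.0) == 50.0

    def test_monotone_increasing_for_positive_activation_energy(self):
        vals = [pc.arrhenius_scale(1.0, 65330.0, tc) for tc in (15, 20, 25, 30, 35)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_matches_hand_evaluated_exponential(self):
        # exp((79430/8.3145) * (1/298.15 - 1/308.15)), evaluated independently
        assert pc.arrhenius_scale(1.0, 79430.0, 35.0, 25.0) == pytest.approx(
            2.828662239926186, rel=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            pc.arrhenius_scale(float("nan"), 65330.0, 25.0)


class TestLeafKinetics:
    def test_reference_point_identities(self):
        kin = pc.leaf_kinetics(25.0, c.P_REF)
        assert kin.gammastar == pytest.approx(c.GAMMASTAR25, rel=1e-12)
        assert kin.kc == pytest.approx(c.KC25, rel=1e-12)
        assert kin.ko == pytest.approx(c.KO25, rel=1e-12)
        assert kin.eta_star == pytest.approx(1.0, abs=1e-15)

    def test_kmm_exceeds_kc_for_positive_o2(self):
        kin = pc.leaf_kinetics(25.0, c.P_REF)
        assert kin.kmm > kin.kc

    def test_fixture_at_30C(self):
        # frozen from an independent scalar evaluation of the same published
        # constants (Arrhenius from 25 degC, kmm = kc*(1 + pO2/ko))
        kin = pc.leaf_kinetics(30.0, 101325.0)
        assert kin.gammastar == pytest.approx(5.571844806328464, rel=1e-12)
        assert kin.kc == pytest.approx(67.80297779728687, rel=1e-12)
        assert kin.ko == pytest.approx(35005.59686604179, rel=1e-12)
        assert kin.kmm == pytest.approx(108.91907844428636, rel=1e-12)
        assert kin.eta_star == pytest.approx(0.9531154753271216, rel=1e-12)

    def test_gammastar_scales_linearly_with_pressure(self):
        k1 = pc.leaf_kinetics(25.0, c.P_REF)
        k2 = pc.leaf_kinetics(25.0, c.P_REF / 2.0)
        assert k2.gammastar == pytest.approx(k1.gammastar / 2.0, rel=1e-12)

    def test_viscosity_monotone_decreasing(self):
        etas = [pc.viscosity_ratio(tc) for tc in range(0, 45, 5)]
        assert all(a > b for a, b in zip(etas, etas[1:]))


class TestChiOptimal:
    def test_chi_is_one_at_zero_vpd(self, params):
        f = pc.MonthlyForcing(tc=25.0, vpd=0.0, co2=400.0, patm=c.P_REF, ppfd=1000.0)
        chi, ci = pc.chi_optimal(f, params)
        assert chi == pytest.approx(1.0, abs=1e-15)
        assert ci == pytest.approx(pc.ambient_co2_pa(400.0, c.P_REF), rel=1e-12)

    def test_chi_strictly_decreases_with_vpd(self, params):
        chis = [pc.chi_optimal(pc.MonthlyForcing(tc=25.0, vpd=v, co2=400.0,
                                                 patm=c.P_REF, ppfd=1000.0), params)[0]
                for v in (0.0, 250.0, 1000.0, 2500.0)]
        assert all(a > b for a, b in zip(chis, chis[1:]))

    def test_standard_conditions_fixture(self, std_forcing, params):
        # frozen from an independent closed-form evaluation:
        # xi = sqrt(146*(kmm25+G*)/1.6), chi = G*/ca + (1-G*/ca)*xi/(xi+sqrt(1000))
        chi, ci = pc.chi_optimal(std_forcing, params)
        assert chi == pytest.approx(0.7532252152711004, rel=1e-12)
        assert ci == pytest.approx(30.5282179749377, rel=1e-12)

    def test_sub_compensation_ca_rejected(self, params):
        f = pc.MonthlyForcing(tc=25.0, vpd=1000.0, co2=1.0, patm=c.P_REF, ppfd=1000.0)
        with pytest.raises(ValueError, match="compensation"):
            pc.chi_optimal(f, params)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(tc=st.floats(5.0, 40.0), vpd=st.floats(0.0, 4000.0),
           co2=st.floats(300.0, 600.0))
    def test_chi_bounded_between_gammastar_ratio_and_one(self, tc, vpd, co2):
        f = pc.MonthlyForcing(tc=tc, vpd=vpd, co2=co2, patm=c.P_REF, ppfd=1000.0)
        kin = pc.leaf_kinetics(tc, c.P_REF)
        chi, _ = pc.chi_optimal(f)
        ca = pc.ambient_co2_pa(co2, c.P_REF)
        assert kin.gammastar / ca < chi <= 1.0


class TestLimitationFactors:
    def test_zero_at_compensation_point(self):
        kin = pc.leaf_kinetics(25.0, c.P_REF)
        mj, mc = pc.limitation_factors(kin.gammastar, kin)
        assert mj == 0.0 and mc == 0.0

    def test_mj_half_at_four_gammastar(self):
        kin = pc.leaf_kinetics(25.0, c.P_REF)
        mj, _ = pc.limitation_factors(4.0 * kin.gammastar, kin)
        assert mj == pytest.approx(0.5, rel=1e-12)

    def test_limits_approach_one(self):
        kin = pc.leaf_kinetics(25.0, c.P_REF)
        mj, mc = pc.limitation_factors(1e9, kin)
        assert mj == pytest.approx(1.0, rel=1e-6)
        assert mc == pytest.approx(1.0, rel=1e-6)

    def test_clamped_below_compensation(self):
        kin = pc.leaf_kinetics(25.0, c.P_REF)
        mj, mc = pc.limitation_factors(kin.gammastar / 2.0, kin)
        assert mj == 0.0 and mc == 0.0


class TestJmaxLimitation:
    def test_zero_at_and_below_cstar(self):
        assert pc.jmax_limitation(0.41, 0.41) == 0.0
        assert pc.jmax_limitation(0.3, 0.41) == 0.0

    def test_approaches_mj_as_cstar_vanishes(self):
        assert pc.jmax_limitation(0.7, 1e-12) == pytest.approx(0.7, rel=1e-6)

    def test_hand_arithmetic_fixture(self):
        # 0.7 * sqrt(1 - (0.41/0.7)^(2/3))
        assert pc.jmax_limitation(0.7, 0.41) == pytest.approx(
            0.38337917660050336, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(mj=st.floats(0.0, 1.0))
    def test_mprime_never_exceeds_mj(self, mj):
        mprime = pc.jmax_limitation(mj, 0.41)
        assert 0.0 <= mprime <= mj
        assert (mprime == 0.0) == (mj <= 0.41)


class TestLue:
    def test_scales_linearly_in_phi0(self, std_forcing):
        l1 = pc.lue(std_forcing, pc.PhotoParams(phi0=0.04))
        l2 = pc.lue(std_forcing, pc.PhotoParams(phi0=0.08))
        assert l2 == pytest.approx(2.0 * l1, rel=1e-12)

    def test_zero_when_mj_below_cstar(self, params):
        # hot, CO2-poor, dry: ci low enough that mj <= c*
        f = pc.MonthlyForcing(tc=45.0, vpd=4000.0, co2=150.0, patm=c.P_REF,
                              ppfd=1000.0)
        assert pc.lue(f, params) == 0.0

    def test_standard_conditions_fixture(self, std_forcing, params):
        # product of the oracle-pinned chi -> mj -> m' chain times phi0*Mc
        assert pc.lue(std_forcing, params) == pytest.approx(
            0.2116664417574114, rel=1e-12)

    def test_temperature_dependent_phi0_mode_normalised_at_25C(self, std_forcing):
        p_fix = pc.PhotoParams(phi0=0.05, phi0_temp_dependent=False)
        p_var = pc.PhotoParams(phi0=0.05, phi0_temp_dependent=True)
        assert pc.lue(std_forcing, p_var) == pytest.approx(
            pc.lue(std_forcing, p_fix), rel=1e-12)


class TestGpp:
    def test_annihilation_and_linearity(self):
        assert pc.gpp(0.0, 0.35, 1000.0) == 0.0
        assert pc.gpp(0.5, 0.35, 2000.0) == pytest.approx(
            2.0 * pc.gpp(0.5, 0.35, 1000.0), rel=1e-12)

    def test_arithmetic_product(self):
        assert pc.gpp(0.95, 0.35, 1000.0) == pytest.approx(332.5, rel=1e-12)

    def test_fapar_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pc.gpp(1.2, 0.35, 1000.0)

    def test_additive_over_split_periods(self):
        whole = pc.gpp(0.9, 0.3, 1000.0)
        halves = pc.gpp(0.9, 0.3, 500.0) + pc.gpp(0.9, 0.3, 500.0)
        assert whole == pytest.approx(halves, rel=1e-12)


class TestVcmaxAndCoordination:
    def test_zero_at_zero_light(self, std_forcing, params):
        assert pc.vcmax_optimal(std_forcing, params, 0.0) == 0.0

    def test_coordination_identity_random_forcings(self, params, rng):
        """Ac at the optimal Vcmax equals AJ at the coordinated Jmax."""
        for _ in range(300):
            f = random_forcing(rng)
            iabs = float(rng.uniform(100.0, 1500.0))
            res = pc.optimality(f, params, iabs=iabs)
            if res.mprime == 0.0:
                continue
            kin = pc.leaf_kinetics(f.tc, f.patm, params.o2_frac)
            ac = pc.assimilation_ac(pc.vcmax_optimal(f, params, iabs), res.ci, kin)
            aj = pc.assimilation_aj(pc.jmax_implied(f, params, iabs),
                                    params.phi0_at(f.tc), iabs, res.ci, kin)
            assert ac == pytest.approx(aj, rel=1e-6)

    def test_unlimited_variant_uses_mj(self, std_forcing, params):
        res = pc.optimality(std_forcing, params, iabs=800.0)
        v_lim = pc.vcmax_optimal(std_forcing, params, 800.0, limited=True)
        v_unl = pc.vcmax_optimal(std_forcing, params, 800.0, limited=False)
        assert v_unl == pytest.approx(v_lim * res.mj / res.mprime, rel=1e-12)


class TestAssimilation:
    def test_ac_zero_at_compensation_and_linear_in_vcmax(self):
        kin = pc.leaf_kinetics(25.0, c.P_REF)
        assert pc.assimilation_ac(30.0, kin.gammastar, kin) == 0.0
        a1 = pc.assimilation_ac(30.0, 30.0, kin)
        assert pc.assimilation_ac(60.0, 30.0, kin) == pytest.approx(2 * a1, rel=1e-12)

    def test_ac_half_vcmax_when_mc_is_half(self):
        # ci such that (ci - G*)/(ci + kmm) = 0.5  =>  ci = 2 G* + kmm
        kin = pc.leaf_kinetics(25.0, c.P_REF)
        ci = 2.0 * kin.gammastar + kin.kmm
        assert pc.assimilation_ac(30.0, ci, kin) == pytest.approx(15.0, rel=1e-12)

    def test_electron_transport_limits(self):
        # saturating at high light; linear in light at low light
        assert pc.electron_transport(0.05, 1e9, 100.0) == pytest.approx(100.0, rel=1e-4)
        x = 4 * 0.05 * 1e-3
        assert pc.electron_transport(0.05, 1e-3, 100.0) == pytest.approx(x, rel=1e-6)

    def test_aj_hand_arithmetic_at_chamber_conditions(self):
        # phi0=0.05, iabs=2000 (chamber PPFD), jmax=100:
        # J = 400/sqrt(1+16) = 97.0142...
        kin = pc.leaf_kinetics(25.0, c.P_REF)
        j = pc.electron_transport(0.05, 2000.0, 100.0)
        assert j == pytest.approx(97.01425001453319, rel=1e-12)
        ci = 30.0
        mj = (ci - kin.gammastar) / (ci + 2 * kin.gammastar)
        assert pc.assimilation_aj(100.0, 0.05, 2000.0, ci, kin) == pytest.approx(
            j / 4.0 * mj, rel=1e-12)

    def test_aj_rejects_nonpositive_jmax(self):
        kin = pc.leaf_kinetics(25.0, c.P_REF)
        with pytest.raises(ValueError):
            pc.assimilation_aj(0.0, 0.05, 2000.0, 30.0, kin)


class TestForcingValidation:
    @pytest.mark.parametrize("kw", [
        dict(vpd=-1.0), dict(ppfd=-5.0), dict(co2=0.0), dict(patm=0.0),
        dict(tc=70.0), dict(tc=float("nan")),
    ])
    def test_invalid_forcing_rejected(self, kw):
        base = dict(tc=25.0, vpd=1000.0, co2=400.0, patm=c.P_REF, ppfd=1000.0)
        base.update(kw)
        with pytest.raises(ValueError):
            pc.MonthlyForcing(**base)

    def test_ppfd_from_shortwave_default_conversion(self):
        # 1 MJ of shortwave -> 2.04 mol photons
        assert pc.ppfd_from_shortwave(1e6) == pytest.approx(2.04, rel=1e-12)
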