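"""FvCB leaf biochemistry and the optimality-based LUE model.

This module implements the photosynthesis core shared by every GPP
experiment: Arrhenius temperature kinetics, the least-cost prediction of
the ci/ca ratio (chi), the CO2 limitation factors of the FvCB model, the
Jmax-limitation adjustment, light use efficiency (LUE), and the
optimality-predicted Vcmax with its coordinated Jmax.

The model chain is

    chi -> ci -> (mj, mc) -> m' -> LUE = phi0 * m' * Mc

with GPP = fAPAR * LUE * PPFD aggregated over monthly records. The
canopy is treated as one big leaf absorbing fAPAR * PPFD; C3
photosynthesis only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import constants as c

__all__ = [
    "MonthlyForcing",
    "LeafKinetics",
    "OptimalityResult",
    "PhotoParams",
    "arrhenius_scale",
    "viscosity_ratio",
    "leaf_kinetics",
    "ambient_co2_pa",
    "chi_optimal",
    "limitation_factors",
    "jmax_limitation",
    "lue",
    "optimality",
    "gpp",
    "vcmax_optimal",
    "jmax_implied",
    "assimilation_ac",
    "assimilation_aj",
    "electron_transport",
    "ppfd_from_shortwave",
]


@dataclass(frozen=True)
class MonthlyForcing:
    """One site-month of climate drivers.

    tc: air temperature, degC
    vpd: vapour pressure deficit, Pa
    co2: ambient CO2 mole fraction, umol mol-1
    patm: surface pressure, Pa
    ppfd: photosynthetic photon flux density, mol photons m-2 month-1
    """

    tc: float
    vpd: float
    co2: float
    patm: float
    ppfd: float
    month_index: int = 1
    year: int = 0

    def __post_init__(self) -> None:
        for name in ("tc", "vpd", "co2", "patm", "ppfd"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite forcing field {name!r}: {v}")
        if self.vpd < 0:
            raise ValueError(f"vpd must be >= 0, got {self.vpd}")
        if self.ppfd < 0:
            raise ValueError(f"ppfd must be >= 0, got {self.ppfd}")
        if self.co2 <= 0 or self.patm <= 0:
            raise ValueError("co2 and patm must be positive")
        if not -10.0 < self.tc < 60.0:
            raise ValueError(f"tc outside plausible range (-10, 60): {self.tc}")
        if not 1 <= self.month_index <= 12:
            raise ValueError(f"month_index must be 1..12, got {self.month_index}")


@dataclass(frozen=True)
class LeafKinetics:
    """Temperature/pressure-adjusted kinetic coefficients (Pa, unitless)."""

    gammastar: float
    kc: float
    ko: float
    kmm: float
    eta_star: float


@dataclass(frozen=True)
class OptimalityResult:
    """Optimality model outputs for one forcing record."""

    chi: float
    ci: float
    mj: float
    mc: float
    mprime: float
    lue: float
    vcmax_opt: float


@dataclass(frozen=True)
class PhotoParams:
    """Tunable constants of the optimality model.

    phi0: intrinsic quantum yield, mol C mol-1 photons. Fixed by default;
        set ``phi0_temp_dependent=True`` for the quadratic temperature
        response variant (phi0 then acts as the value at 25 degC,
        rescaled by the published quadratic shape).
    beta: unit-cost ratio of maintaining carboxylation vs. transpiration
        capacity (dimensionless).
    cstar: cost parameter governing Jmax limitation.
    """

    phi0: float = 0.05
    beta: float = 146.0
    cstar: float = 0.41
    mc_mass: float = c.MC_CARBON
    o2_frac: float = c.O2_FRAC
    phi0_temp_dependent: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.phi0 <= 0.125:
            raise ValueError(f"phi0 must be in (0, 0.125], got {self.phi0}")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0.0 < self.cstar < 1.0:
            raise ValueError("cstar must be in (0, 1)")

    def phi0_at(self, tc: float) -> float:
        """Quantum yield at temperature tc.

        The temperature-dependent mode uses the standard quadratic shape
        for the maximum quantum yield of C3 photosynthesis,
        (0.352 + 0.022 tc - 3.4e-4 tc^2) / 8, normalised so that
        phi0_at(25) == phi0.
        """
        if not self.phi0_temp_dependent:
            return self.phi0
        shape = 0.352 + 0.022 * tc - 3.4e-4 * tc * tc
        shape25 = 0.352 + 0.022 * 25.0 - 3.4e-4 * 25.0 * 25.0
        return max(0.0, self.phi0 * shape / shape25)


def arrhenius_scale(rate_ref: float, dha: float, tc: float, tc_ref: float = c.TC_REF) -> float:
    """Scale a rate from tc_ref to tc with activation energy dha (J mol-1).

    Returns rate_ref * exp[(dha / R) * (1/T_ref - 1/T)] with T in kelvin.
    """
    for v in (rate_ref, dha, tc, tc_ref):
        if not math.isfinite(v):
            raise ValueError("non-finite input to arrhenius_scale")
    tk = tc + 273.15
    tk_ref = tc_ref + 273.15
    return rate_ref * math.exp(dha / c.R_GAS * (1.0 / tk_ref - 1.0 / tk))


# Vogel-Fulcher-Tammann correlation for pure-water dynamic viscosity,
# eta(T) = A * exp(B / (T - C)); only the ratio to 25 degC is used, so A
# cancels and eta_star(25 degC) == 1 holds exactly.
_VOGEL_B = 247.8
_VOGEL_C = 140.0


def viscosity_ratio(tc: float) -> float:
    """Water viscosity relative to 25 degC (unitless, monotone decreasing)."""
    tk = tc + 273.15
    tk_ref = c.TC_REF + 273.15
    return math.exp(_VOGEL_B / (tk - _VOGEL_C) - _VOGEL_B / (tk_ref - _VOGEL_C))


def leaf_kinetics(tc: float, patm: float, o2_frac: float = c.O2_FRAC) -> LeafKinetics:
    """Kinetic coefficients at leaf temperature tc (degC) and pressure patm (Pa).

    Gamma*, Kc and Ko follow Arrhenius scaling from their 25 degC
    reference constants; Gamma* additionally scales linearly with
    pressure relative to the reference pressure. kmm is the effective
    Michaelis-Menten coefficient K = Kc * (1 + pO2 / Ko).
    """
    if not (math.isfinite(tc) and math.isfinite(patm)) or patm <= 0:
        raise ValueError("invalid tc/patm for leaf_kinetics")
    gammastar = (
        arrhenius_scale(c.GAMMASTAR25, c.DHA_GAMMASTAR, tc) * patm / c.P_REF
    )
    kc = arrhenius_scale(c.KC25, c.DHA_KC, tc)
    ko = arrhenius_scale(c.KO25, c.DHA_KO, tc)
    po2 = patm * o2_frac
    kmm = kc * (1.0 + po2 / ko)
    return LeafKinetics(
        gammastar=gammastar, kc=kc, ko=ko, kmm=kmm, eta_star=viscosity_ratio(tc)
    )


def ambient_co2_pa(co2_umol_mol: float, patm: float) -> float:
    """Ambient CO2 partial pressure (Pa) from mole fraction and pressure."""
    return co2_umol_mol * 1e-6 * patm


def chi_optimal(forcing: MonthlyForcing, params: PhotoParams = PhotoParams()) -> tuple[float, float]:
    """Least-cost optimal ci/ca ratio and ci (Pa).

    chi = Gamma*/ca + (1 - Gamma*/ca) * xi / (xi + sqrt(vpd)) with
    xi = sqrt(beta * (K + Gamma*) / (1.6 * eta*)). At vpd = 0 this gives
    chi = 1 exactly.
    """
    kin = leaf_kinetics(forcing.tc, forcing.patm, params.o2_frac)
    ca = ambient_co2_pa(forcing.co2, forcing.patm)
    if ca <= kin.gammastar:
        raise ValueError(
            f"ambient CO2 ({ca:.3f} Pa) at or below the compensation point "
            f"({kin.gammastar:.3f} Pa): invalid forcing"
        )
    xi = math.sqrt(params.beta * (kin.kmm + kin.gammastar) / (1.6 * kin.eta_star))
    g = kin.gammastar / ca
    chi = g + (1.0 - g) * xi / (xi + math.sqrt(forcing.vpd))
    return chi, chi * ca


def limitation_factors(ci: float, kin: LeafKinetics) -> tuple[float, float]:
    """CO2 limitation factors (mj, mc); clamped to 0 below the compensation point."""
    if ci < 0:
        raise ValueError("ci must be >= 0")
    mj = (ci - kin.gammastar) / (ci + 2.0 * kin.gammastar)
    mc = (ci - kin.gammastar) / (ci + kin.kmm)
    return max(0.0, mj), max(0.0, mc)


def jmax_limitation(mj: float, cstar: float) -> float:
    """Jmax-limitation factor m' = mj * sqrt(1 - (c*/mj)^(2/3)), 0 if mj <= c*."""
    if mj < 0:
        raise ValueError("mj must be >= 0")
    if mj <= cstar:
        return 0.0
    return mj * math.sqrt(1.0 - (cstar / mj) ** (2.0 / 3.0))


def optimality(forcing: MonthlyForcing, params: PhotoParams = PhotoParams(),
               iabs: float = 0.0) -> OptimalityResult:
    """Full optimality prediction for one forcing record.

    iabs: absorbed PPFD (umol m-2 s-1) used for the Vcmax prediction;
    chi, the limitation factors and LUE do not depend on it.
    """
    kin = leaf_kinetics(forcing.tc, forcing.patm, params.o2_frac)
    chi, ci = chi_optimal(forcing, params)
    mj, mc = limitation_factors(ci, kin)
    mprime = jmax_limitation(mj, params.cstar)
    phi0 = params.phi0_at(forcing.tc)
    lue_val = phi0 * mprime * params.mc_mass
    vcmax = phi0 * iabs * mprime / mc if mc > 0 else 0.0
    return OptimalityResult(
        chi=chi, ci=ci, mj=mj, mc=mc, mprime=mprime, lue=lue_val, vcmax_opt=vcmax
    )


def lue(forcing: MonthlyForcing, params: PhotoParams = PhotoParams()) -> float:
    """Optimality-based light use efficiency, gC per mol photons."""
    return optimality(forcing, params).lue


def gpp(fapar: float, lue_gc_mol: float, ppfd: float) -> float:
    """GPP = fAPAR * LUE * PPFD (gC m-2 per the PPFD accumulation period)."""
    if not 0.0 <= fapar <= 1.0:
        raise ValueError(f"fapar must be in [0, 1], got {fapar}")
    return fapar * lue_gc_mol * ppfd


def vcmax_optimal(forcing: MonthlyForcing, params: PhotoParams, iabs: float,
                  limited: bool = True) -> float:
    """Optimality-predicted Vcmax (umol m-2 s-1) at absorbed light iabs.

    limited=True (default) uses the Jmax-limitation-adjusted factor m'
    (vcmax = phi0 * iabs * m' / mc), which is the prediction consistent
    with the LUE path and with a finite coordinated Jmax; limited=False
    uses mj in place of m'.
    """
    res = optimality(forcing, params, iabs=iabs)
    if res.mc == 0.0:
        raise ValueError("sub-compensation conditions: mc = 0")
    factor = res.mprime if limited else res.mj
    return params.phi0_at(forcing.tc) * iabs * factor / res.mc


def jmax_implied(forcing: MonthlyForcing, params: PhotoParams, iabs: float) -> float:
    """Jmax coordinated with vcmax_optimal under the same forcing.

    Solves J(iabs, jmax) = 4 * phi0 * iabs * m'/mj for jmax with the
    saturating electron-transport equation, so that AJ at this Jmax
    equals Ac at the optimal Vcmax (the coordination identity).
    Returns inf when m' == mj (no Jmax limitation).
    """
    res = optimality(forcing, params, iabs=iabs)
    if res.mj <= 0 or res.mprime <= 0:
        raise ValueError("degenerate limitation factors: no coordinated Jmax")
    r = res.mprime / res.mj
    if r >= 1.0:
        return math.inf
    phi0 = params.phi0_at(forcing.tc)
    return 4.0 * phi0 * iabs / math.sqrt(1.0 / (r * r) - 1.0)


def assimilation_ac(vcmax: float, ci: float, kin: LeafKinetics, rd: float = 0.0) -> float:
    """Rubisco-limited assimilation Ac = Vcmax * (ci - G*)/(ci + K) - rd.

    Gross by default (rd = 0); pass rd for the net variant.
    """
    mc = max(0.0, (ci - kin.gammastar) / (ci + kin.kmm))
    return vcmax * mc - rd


def electron_transport(phi0: float, iabs: float, jmax: float) -> float:
    """Saturating electron transport J = 4 phi0 Iabs / sqrt(1 + (4 phi0 Iabs / Jmax)^2)."""
    if jmax <= 0:
        raise ValueError("jmax must be positive")
    x = 4.0 * phi0 * iabs
    if math.isinf(jmax):
        return x
    return x / math.sqrt(1.0 + (x / jmax) ** 2)


def assimilation_aj(jmax: float, phi0: float, iabs: float, ci: float,
                    kin: LeafKinetics, rd: float = 0.0) -> float:
    """Electron-transport-limited assimilation AJ = (J/4) * mj - rd."""
    if iabs < 0:
        raise ValueError("iabs must be >= 0")
    j = electron_transport(phi0, iabs, jmax)
    mj = max(0.0, (ci - kin.gammastar) / (ci + 2.0 * kin.gammastar))
    return j / 4.0 * mj - rd


def ppfd_from_shortwave(sw_j_m2: float | np.ndarray,
                        umol_per_j: float = c.PPFD_PER_SW_J):
    """PPFD (mol photons) from incoming shortwave energy (J), default 2.04 umol/J."""
    return sw_j_m2 * umol_per_j * 1e-6
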