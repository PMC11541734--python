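"""Field gas exchange to photosynthetic traits and trait-based LUE.

Converts two-point gas-exchange measurements — net assimilation at 400
umol mol-1 CO2 and saturating light (Asat) and at 2000 umol mol-1 CO2 and
saturating light (Amax) — into Vcmax and Jmax at the measurement
temperature, normalises them to other temperatures, aggregates species to
a basal-area-weighted community mean (sun leaves only), and computes the
light use efficiency the canopy would have with those measured traits
instead of the optimality-predicted ones.

The inverse Jmax solution uses the same saturating electron-transport
equation as the forward model, so forward simulation followed by
inversion is an exact round trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

from . import constants as c
from . import photo_core as pc

__all__ = [
    "GasExchangeRecord",
    "TraitRecord",
    "CiPolicy",
    "RdPolicy",
    "TraitInversionError",
    "invert_vcmax",
    "invert_jmax",
    "invert_record",
    "derive_traits",
    "normalize_to_temperature",
    "community_weighted_mean",
    "trait_based_lue",
    "growth_temperature",
    "monthly_iabs",
]

#: Seconds of daylight per month used to convert monthly photon totals to a
#: mean daytime flux: ~12 h days year-round (tropical sites), average month
#: length 365.25/12 days.
DAYLIGHT_SECONDS_PER_MONTH = (365.25 / 12.0) * 12.0 * 3600.0


class TraitInversionError(ValueError):
    """A gas-exchange record cannot be inverted to traits."""


@dataclass(frozen=True)
class GasExchangeRecord:
    """One leaf-level measurement (rates in umol m-2 s-1, tleaf degC)."""

    species: str
    plot: str
    asat: float
    amax: float
    tleaf: float
    ppfd_meas: float
    leaf_class: str = "sun"
    basal_area_frac: float = 0.0
    ci_400: float | None = None   # measured ci at 400 ppm, Pa (optional)
    ci_2000: float | None = None  # measured ci at 2000 ppm, Pa (optional)

    def is_valid(self) -> bool:
        return (
            self.asat > 0
            and self.amax >= self.asat
            and self.ppfd_meas > 0
            and self.leaf_class in ("sun", "shade")
        )


@dataclass(frozen=True)
class TraitRecord:
    """Species-level traits with a basal-area weight."""

    species: str
    vcmax_gt: float
    jmax_gt: float
    vcmax25: float
    jmax25: float
    rd: float
    basal_area_frac: float

    def __post_init__(self) -> None:
        for name in ("vcmax_gt", "jmax_gt", "vcmax25", "jmax25", "rd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.basal_area_frac <= 1.0:
            raise ValueError("basal_area_frac must be in [0, 1]")


@dataclass(frozen=True)
class CiPolicy:
    """ci at the measurement as a fraction of ambient ca.

    Stomatal limitation weakens at high CO2, hence the larger default
    ratio at 2000 ppm. Measured ci columns, when present on a record,
    take precedence.
    """

    ratio_400: float = 0.7
    ratio_2000: float = 0.9
    patm: float = c.P_REF

    def ci_at(self, co2_umol_mol: float) -> float:
        ca = pc.ambient_co2_pa(co2_umol_mol, self.patm)
        ratio = self.ratio_400 if co2_umol_mol <= 1000 else self.ratio_2000
        return ratio * ca


@dataclass(frozen=True)
class RdPolicy:
    """Dark respiration policy: rd = frac_of_vcmax * Vcmax, or a fixed value."""

    frac_of_vcmax: float = 0.015
    fixed: float | None = None

    def rd_for(self, vcmax: float) -> float:
        if self.fixed is not None:
            return self.fixed
        return self.frac_of_vcmax * vcmax


def invert_vcmax(rec: GasExchangeRecord, kin: pc.LeafKinetics,
                 rd_policy: RdPolicy = RdPolicy(),
                 ci_policy: CiPolicy = CiPolicy()) -> tuple[float, float]:
    """Vcmax (and rd) at tleaf from Asat, assuming Rubisco limitation.

    Solves asat = Vcmax * mc - rd for Vcmax at ci given by the ci policy
    (or the record's measured ci). Returns (vcmax, rd).
    """
    ci = rec.ci_400 if rec.ci_400 is not None else ci_policy.ci_at(400.0)
    if ci <= kin.gammastar:
        raise TraitInversionError(
            f"ci at measurement ({ci:.2f} Pa) at or below Gamma* "
            f"({kin.gammastar:.2f} Pa)"
        )
    mc = (ci - kin.gammastar) / (ci + kin.kmm)
    if rd_policy.fixed is not None:
        vcmax = (rec.asat + rd_policy.fixed) / mc
        return vcmax, rd_policy.fixed
    if mc <= rd_policy.frac_of_vcmax:
        raise TraitInversionError("mc does not exceed the rd fraction; no solution")
    vcmax = rec.asat / (mc - rd_policy.frac_of_vcmax)
    return vcmax, rd_policy.frac_of_vcmax * vcmax


def invert_jmax(rec: GasExchangeRecord, kin: pc.LeafKinetics, phi0: float,
                rd: float, ci_policy: CiPolicy = CiPolicy()) -> float:
    """Jmax at tleaf from Amax at saturating CO2 and light.

    Solves AJ = (J/4) * mj = amax + rd for the required electron transport
    J, then inverts the saturating J(Iabs, Jmax) equation. A required J at
    or beyond the light-limited asymptote 4*phi0*Iabs has no solution.
    """
    ci = rec.ci_2000 if rec.ci_2000 is not None else ci_policy.ci_at(2000.0)
    if ci <= kin.gammastar:
        raise TraitInversionError("ci at 2000 ppm at or below Gamma*")
    mj = (ci - kin.gammastar) / (ci + 2.0 * kin.gammastar)
    j_req = 4.0 * (rec.amax + rd) / mj
    j_asym = 4.0 * phi0 * rec.ppfd_meas
    if j_req >= j_asym:
        raise TraitInversionError(
            f"required J ({j_req:.1f}) reaches the light-limited asymptote "
            f"({j_asym:.1f}): Amax inconsistent with phi0 and chamber PPFD"
        )
    return j_req / math.sqrt(1.0 - (j_req / j_asym) ** 2)


def invert_record(rec: GasExchangeRecord, phi0: float = 0.05,
                  rd_policy: RdPolicy = RdPolicy(),
                  ci_policy: CiPolicy = CiPolicy(),
                  growth_tc: float = 25.0) -> tuple[TraitRecord, list[str]]:
    """Full inversion of one record to a TraitRecord plus post-hoc flags.

    The returned traits are at the leaf (block) temperature; vcmax25 and
    jmax25 are Arrhenius-normalised. A record whose fitted traits imply
    Ac > AJ at the 400-ppm point violates the Rubisco-limitation
    assumption and is flagged (not rejected).
    """
    flags: list[str] = []
    if not rec.is_valid():
        raise TraitInversionError(f"invalid gas-exchange record for {rec.species}")
    kin = pc.leaf_kinetics(rec.tleaf, ci_policy.patm)
    vcmax, rd = invert_vcmax(rec, kin, rd_policy, ci_policy)
    jmax = invert_jmax(rec, kin, phi0, rd, ci_policy)
    # post-hoc: at 400 ppm, Rubisco limitation requires Ac <= AJ
    ci400 = rec.ci_400 if rec.ci_400 is not None else ci_policy.ci_at(400.0)
    ac = pc.assimilation_ac(vcmax, ci400, kin)
    aj = pc.assimilation_aj(jmax, phi0, rec.ppfd_meas, ci400, kin)
    if ac > aj * (1.0 + 1e-9):
        flags.append("ac_exceeds_aj_at_400ppm")
    trait = TraitRecord(
        species=rec.species,
        vcmax_gt=pc.arrhenius_scale(vcmax, c.DHA_VCMAX, growth_tc, rec.tleaf),
        jmax_gt=pc.arrhenius_scale(jmax, c.DHA_JMAX, growth_tc, rec.tleaf),
        vcmax25=pc.arrhenius_scale(vcmax, c.DHA_VCMAX, 25.0, rec.tleaf),
        jmax25=pc.arrhenius_scale(jmax, c.DHA_JMAX, 25.0, rec.tleaf),
        rd=pc.arrhenius_scale(rd, c.DHA_RD, growth_tc, rec.tleaf),
        basal_area_frac=rec.basal_area_frac,
    )
    return trait, flags


def derive_traits(df: pd.DataFrame, phi0: float = 0.05,
                  rd_policy: RdPolicy = RdPolicy(),
                  ci_policy: CiPolicy = CiPolicy(),
                  growth_tc: float = 25.0) -> tuple[list[TraitRecord], dict]:
    """Invert a gas-exchange table to species traits, sun leaves only.

    Species-level traits are the mean over that species' valid sun-leaf
    records. Records failing validity or inversion are excluded and
    counted in the returned log dict.
    """
    log = {"n_records": len(df), "n_excluded": 0, "n_flagged": 0, "excluded": [],
           "flags": []}
    per_species: dict[str, list[TraitRecord]] = {}
    weights: dict[str, float] = {}
    for i, row in df.iterrows():
        rec = GasExchangeRecord(
            species=str(row["species"]), plot=str(row.get("plot", "")),
            asat=float(row["asat"]), amax=float(row["amax"]),
            tleaf=float(row["tleaf"]), ppfd_meas=float(row["ppfd_meas"]),
            leaf_class=str(row.get("leaf_class", "sun")),
            basal_area_frac=float(row.get("basal_area_frac", 0.0)),
            ci_400=float(row["ci_400"]) if "ci_400" in row and pd.notna(row["ci_400"]) else None,
            ci_2000=float(row["ci_2000"]) if "ci_2000" in row and pd.notna(row["ci_2000"]) else None,
        )
        if rec.leaf_class != "sun":
            continue
        try:
            trait, flags = invert_record(rec, phi0, rd_policy, ci_policy, growth_tc)
        except TraitInversionError as exc:
            log["n_excluded"] += 1
            log["excluded"].append(f"row {i} ({rec.species}): {exc}")
            continue
        if flags:
            log["n_flagged"] += 1
            log["flags"].append(f"row {i} ({rec.species}): {','.join(flags)}")
        per_species.setdefault(rec.species, []).append(trait)
        weights[rec.species] = rec.basal_area_frac
    traits = []
    for sp, recs in per_species.items():
        n = len(recs)
        traits.append(TraitRecord(
            species=sp,
            vcmax_gt=sum(t.vcmax_gt for t in recs) / n,
            jmax_gt=sum(t.jmax_gt for t in recs) / n,
            vcmax25=sum(t.vcmax25 for t in recs) / n,
            jmax25=sum(t.jmax25 for t in recs) / n,
            rd=sum(t.rd for t in recs) / n,
            basal_area_frac=weights[sp],
        ))
    return traits, log


def normalize_to_temperature(trait: TraitRecord, tc_from: float, tc_to: float) -> TraitRecord:
    """Arrhenius-shift vcmax_gt/jmax_gt/rd from tc_from to tc_to."""
    return replace(
        trait,
        vcmax_gt=pc.arrhenius_scale(trait.vcmax_gt, c.DHA_VCMAX, tc_to, tc_from),
        jmax_gt=pc.arrhenius_scale(trait.jmax_gt, c.DHA_JMAX, tc_to, tc_from),
        rd=pc.arrhenius_scale(trait.rd, c.DHA_RD, tc_to, tc_from),
    )


def community_weighted_mean(traits: list[TraitRecord]) -> TraitRecord:
    """Basal-area-weighted community mean trait record.

    Weights are renormalised to sum to 1 over the sampled species (the
    sampling covers ~80% of plot basal area, so raw fractions sum below
    1).
    """
    if not traits:
        raise ValueError("community_weighted_mean needs at least one trait record")
    wtot = sum(t.basal_area_frac for t in traits)
    if wtot <= 0:
        raise ValueError("total basal-area weight is zero")
    def wmean(attr: str) -> float:
        return sum(getattr(t, attr) * t.basal_area_frac for t in traits) / wtot
    return TraitRecord(
        species="CWM",
        vcmax_gt=wmean("vcmax_gt"),
        jmax_gt=wmean("jmax_gt"),
        vcmax25=wmean("vcmax25"),
        jmax25=wmean("jmax25"),
        rd=wmean("rd"),
        basal_area_frac=min(1.0, wtot),
    )


def growth_temperature(forcing: pd.DataFrame | list[pc.MonthlyForcing]) -> float:
    """Site growth temperature: mean air temperature of the forcing series."""
    if isinstance(forcing, pd.DataFrame):
        return float(forcing["tc"].mean())
    return sum(f.tc for f in forcing) / len(forcing)


def monthly_iabs(fapar: float, ppfd_month: float,
                 daylight_seconds: float = DAYLIGHT_SECONDS_PER_MONTH) -> float:
    """Mean daytime absorbed PPFD (umol m-2 s-1) from a monthly total (mol m-2)."""
    return fapar * ppfd_month * 1e6 / daylight_seconds


def trait_based_lue(cwm: TraitRecord, forcing: pc.MonthlyForcing,
                    params: pc.PhotoParams, iabs: float,
                    growth_tc: float | None = None) -> float:
    """LUE (gC per mol photons) with measured traits instead of optimal ones.

    Gross canopy assimilation min(Ac, AJ) at absorbed flux iabs
    (umol m-2 s-1), divided by iabs, times the molar mass of carbon.
    chi (hence ci and the limitation factors) is still the optimality
    prediction; only Vcmax and Jmax come from the field. Traits at growth
    temperature are Arrhenius-shifted to the month's temperature when
    growth_tc is given.
    """
    if iabs < 0:
        raise ValueError("iabs must be >= 0")
    if iabs == 0.0:
        return 0.0
    trait = cwm
    if growth_tc is not None and growth_tc != forcing.tc:
        trait = normalize_to_temperature(cwm, growth_tc, forcing.tc)
    kin = pc.leaf_kinetics(forcing.tc, forcing.patm, params.o2_frac)
    _, ci = pc.chi_optimal(forcing, params)
    phi0 = params.phi0_at(forcing.tc)
    ac = pc.assimilation_ac(trait.vcmax_gt, ci, kin)
    aj = pc.assimilation_aj(trait.jmax_gt, phi0, iabs, ci, kin)
    a_gross = max(0.0, min(ac, aj))
    return a_gross / iabs * params.mc_mass
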