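"""Factorial GPP experiments and data-model discrepancy decomposition.

Every experiment computes GPP through the same equation,
GPP = fAPAR * LUE * PPFD, summed over months and averaged over years;
experiments differ only in which source each input is bound to:

========== =========== =================== ============
experiment LUE         fAPAR               PPFD
========== =========== =================== ============
Pmodel_PfL field traits field               field
Pmodel_Pf  optimality  field               field
Pmodel_P   optimality  satellite filtered  field
Pmodel_null optimality satellite filtered  product
product    lookup table satellite filtered product
========== =========== =================== ============

The discrepancy between biometric (bottom-up field) GPP and a
satellite-product GPP then telescopes exactly into four terms:

    unresolved   = biometric - PfL
    traits       = PfL - Pf        (field vs optimality LUE)
    fapar        = Pf - P          (field vs satellite fAPAR)
    optimisation = P - product     (optimality vs lookup-table LUE,
                                    folding in the PPFD source; the PPFD
                                    sub-term P - null is reported
                                    separately)

The lookup-table product emulator mirrors the classic satellite GPP
algorithm: a biome maximum LUE deflated by linear temperature and VPD
ramps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import constants as c
from . import photo_core as pc
from . import traits as tr
from . import fapar as fp
from . import biometric as bm

__all__ = [
    "ExperimentSpec",
    "EXPERIMENTS",
    "BiomeLookupParams",
    "SiteInputs",
    "AttributionLedger",
    "lookup_lue",
    "lookup_lue_gpp",
    "run_experiment",
    "run_all_experiments",
    "decompose",
    "composite_gpp",
    "forest_only_gpp",
    "forcing_bias_report",
    "attribute_site",
]

_LUE_SOURCES = ("optimality", "traits", "lookup")
_FAPAR_SOURCES = ("field", "satellite_filtered")
_PPFD_SOURCES = ("field", "product")


@dataclass(frozen=True)
class ExperimentSpec:
    """Input bindings for one GPP experiment."""

    name: str
    lue_source: str
    fapar_source: str
    ppfd_source: str

    def __post_init__(self) -> None:
        if self.lue_source not in _LUE_SOURCES:
            raise ValueError(f"unknown lue_source {self.lue_source!r}")
        if self.fapar_source not in _FAPAR_SOURCES:
            raise ValueError(f"unknown fapar_source {self.fapar_source!r}")
        if self.ppfd_source not in _PPFD_SOURCES:
            raise ValueError(f"unknown ppfd_source {self.ppfd_source!r}")


EXPERIMENTS: dict[str, ExperimentSpec] = {
    "Pmodel_PfL": ExperimentSpec("Pmodel_PfL", "traits", "field", "field"),
    "Pmodel_Pf": ExperimentSpec("Pmodel_Pf", "optimality", "field", "field"),
    "Pmodel_P": ExperimentSpec("Pmodel_P", "optimality", "satellite_filtered", "field"),
    "Pmodel_null": ExperimentSpec("Pmodel_null", "optimality", "satellite_filtered", "product"),
    "product": ExperimentSpec("product", "lookup", "satellite_filtered", "product"),
}


@dataclass(frozen=True)
class BiomeLookupParams:
    """Lookup-table LUE parameters for one biome.

    epsilon_max: maximum LUE in gC per mol photons (the published
    evergreen-broadleaf value of 1.268 gC per MJ of absorbed PAR converts
    with 4.6 umol photons per J of PAR). tmin ramp rises 0 -> 1 between
    tmin_min and tmin_max (degC); vpd ramp falls 1 -> 0 between vpd_min
    and vpd_max (Pa). The published ramps are defined on *daytime* VPD;
    monthly-mean VPD forcing is multiplied by vpd_daytime_factor before
    entering the ramp.
    """

    epsilon_max: float = 1.268 / (c.PPFD_PER_PAR_J * 1e-6) * 1e-6  # gC mol-1
    tmin_min: float = -8.0
    tmin_max: float = 9.09
    vpd_min: float = 800.0
    vpd_max: float = 3100.0
    vpd_daytime_factor: float = 1.75

    def __post_init__(self) -> None:
        if not (self.tmin_max > self.tmin_min and self.vpd_max > self.vpd_min):
            raise ValueError("ramp bounds must be strictly ordered")


def _ramp_up(x: float, lo: float, hi: float) -> float:
    return min(1.0, max(0.0, (x - lo) / (hi - lo)))


def lookup_lue(tc: float, vpd: float, biome: BiomeLookupParams) -> float:
    """Lookup-table LUE (gC per mol photons) = eps_max * f(Tmin) * f(VPD)."""
    f_t = _ramp_up(tc, biome.tmin_min, biome.tmin_max)
    f_vpd = 1.0 - _ramp_up(vpd * biome.vpd_daytime_factor, biome.vpd_min, biome.vpd_max)
    return biome.epsilon_max * f_t * f_vpd


@dataclass
class SiteInputs:
    """Everything a site's experiments can bind to.

    forcing_field / forcing_product: DataFrames with columns
    (year, month, tc, vpd, co2, patm, ppfd); ppfd in mol m-2 month-1.
    fapar_field / fapar_satellite: monthly climatologies (12 values,
    index 1..12; NaN = missing month, filled with the mean of available
    months at run time).
    """

    site: str
    forcing_field: pd.DataFrame
    forcing_product: pd.DataFrame
    fapar_field: pd.Series
    fapar_satellite: pd.Series
    cwm: tr.TraitRecord | None = None
    growth_tc: float | None = None
    params: pc.PhotoParams = dc_field(default_factory=pc.PhotoParams)
    biome: BiomeLookupParams = dc_field(default_factory=BiomeLookupParams)


def _fill_climatology(clim: pd.Series) -> pd.Series:
    """Replace missing months by the mean of available months (reported, not hidden)."""
    if clim.isna().all():
        raise ValueError("fAPAR climatology has no surviving months")
    return clim.fillna(clim.mean(skipna=True))


def run_experiment(spec: ExperimentSpec | str, inputs: SiteInputs) -> float:
    """Annual GPP (MgC ha-1 yr-1) for one experiment: Eq. GPP = fAPAR*LUE*PPFD.

    Monthly GPP is summed per calendar year and averaged across the years
    present in the forcing table. All experiments share this code path;
    only the bindings differ.
    """
    if isinstance(spec, str):
        spec = EXPERIMENTS[spec]
    if spec.lue_source == "traits":
        if inputs.cwm is None:
            raise ValueError(
                f"experiment {spec.name!r} binds lue_source='traits' but no "
                "community trait record is present"
            )
    if spec.ppfd_source == "product" and inputs.forcing_product is None:
        raise ValueError(f"experiment {spec.name!r} needs product forcing")

    clim = inputs.fapar_field if spec.fapar_source == "field" else inputs.fapar_satellite
    clim = _fill_climatology(clim)

    met = inputs.forcing_field.copy()
    if spec.ppfd_source == "product":
        prod = inputs.forcing_product[["year", "month", "ppfd"]]
        met = met.drop(columns=["ppfd"]).merge(prod, on=["year", "month"], how="inner")
        if met.empty:
            raise ValueError("field and product forcing share no year-months")

    annual: dict[int, float] = {}
    for row in met.itertuples(index=False):
        forcing = pc.MonthlyForcing(
            tc=row.tc, vpd=row.vpd, co2=row.co2, patm=row.patm, ppfd=row.ppfd,
            month_index=int(row.month), year=int(row.year),
        )
        fapar_m = float(clim.loc[int(row.month)])
        if spec.lue_source == "optimality":
            lue_m = pc.lue(forcing, inputs.params)
        elif spec.lue_source == "traits":
            iabs = tr.monthly_iabs(fapar_m, forcing.ppfd)
            lue_m = tr.trait_based_lue(inputs.cwm, forcing, inputs.params, iabs,
                                       growth_tc=inputs.growth_tc)
        else:
            lue_m = lookup_lue(forcing.tc, forcing.vpd, inputs.biome)
        annual[forcing.year] = annual.get(forcing.year, 0.0) + pc.gpp(
            fapar_m, lue_m, forcing.ppfd
        )
    mean_gc_m2 = float(np.mean(list(annual.values())))
    return mean_gc_m2 * c.GC_M2_TO_MGC_HA


def run_all_experiments(inputs: SiteInputs) -> dict[str, float]:
    """All five experiments for one site, MgC ha-1 yr-1."""
    return {name: run_experiment(spec, inputs) for name, spec in EXPERIMENTS.items()}


def lookup_lue_gpp(inputs: SiteInputs) -> float:
    """Annual GPP of the lookup-table product emulator (MgC ha-1 yr-1)."""
    return run_experiment(EXPERIMENTS["product"], inputs)


@dataclass(frozen=True)
class AttributionLedger:
    """Decomposition of the biometric-minus-product GPP discrepancy.

    All terms in MgC ha-1 yr-1; total = unresolved + traits_term +
    fapar_term + optimisation_term holds exactly by construction.
    """

    site: str
    biometric: float
    pfl: float
    pf: float
    p: float
    product: float

    @property
    def unresolved(self) -> float:
        return self.biometric - self.pfl

    @property
    def traits_term(self) -> float:
        return self.pfl - self.pf

    @property
    def fapar_term(self) -> float:
        return self.pf - self.p

    @property
    def optimisation_term(self) -> float:
        return self.p - self.product

    @property
    def total(self) -> float:
        return self.biometric - self.product

    def percent_of_biometric(self) -> dict[str, float]:
        if self.biometric == 0:
            raise ZeroDivisionError("biometric GPP is zero")
        return {
            k: 100.0 * getattr(self, k) / self.biometric
            for k in ("unresolved", "traits_term", "fapar_term",
                      "optimisation_term", "total")
        }

    def as_dict(self) -> dict[str, float]:
        return {
            "site": self.site,
            "biometric": self.biometric,
            "Pmodel_PfL": self.pfl,
            "Pmodel_Pf": self.pf,
            "Pmodel_P": self.p,
            "product": self.product,
            "unresolved": self.unresolved,
            "traits_term": self.traits_term,
            "fapar_term": self.fapar_term,
            "optimisation_term": self.optimisation_term,
            "total": self.total,
        }


def decompose(biometric: float, pfl: float, pf: float, p: float, product: float,
              site: str = "") -> AttributionLedger:
    """Build the attribution ledger from the five site-level annual GPPs."""
    return AttributionLedger(site=site, biometric=biometric, pfl=pfl, pf=pf,
                             p=p, product=product)


def composite_gpp(pft_table: pd.DataFrame) -> float:
    """Gridcell GPP = sum of fraction * GPP over PFTs (residual = bare ground).

    pft_table columns: pft, fraction, gpp[, is_forest].
    """
    frac = pft_table["fraction"].astype(float)
    if (frac < 0).any():
        raise ValueError("PFT cover fractions must be >= 0")
    if frac.sum() > 1.0 + 1e-9:
        raise ValueError("PFT cover fractions sum above 1")
    return float((frac * pft_table["gpp"].astype(float)).sum())


def forest_only_gpp(pft_table: pd.DataFrame) -> float:
    """Cover-weighted mean GPP over forest PFTs: the grid cell if all forest."""
    forest = pft_table[pft_table["is_forest"].astype(bool)]
    wsum = float(forest["fraction"].astype(float).sum())
    if wsum <= 0:
        raise ValueError("no forest cover in the PFT table")
    return float((forest["fraction"].astype(float) * forest["gpp"].astype(float)).sum() / wsum)


def forcing_bias_report(series_field: pd.DataFrame, series_product: pd.DataFrame,
                        variables: tuple[str, ...] = ("tc", "vpd", "ppfd"),
                        inputs: SiteInputs | None = None) -> dict:
    """Product-minus-field bias, RMSE and seasonal profile per climate variable.

    With ``inputs`` given, a GPP-sensitivity column is added: the
    Pmodel_Pf GPP recomputed with that single variable swapped to the
    product series, minus the baseline — i.e. how much of the GPP
    discrepancy that variable's bias could explain.
    """
    merged = series_field.merge(series_product, on=["year", "month"],
                                suffixes=("_field", "_product"), how="inner")
    if merged.empty:
        raise ValueError("field and product forcing series share no year-months")
    if len(merged) != len(series_field) or len(merged) != len(series_product):
        raise ValueError("field and product forcing series are misaligned")
    report: dict[str, dict] = {}
    baseline = run_experiment("Pmodel_Pf", inputs) if inputs is not None else None
    for var in variables:
        diff = merged[f"{var}_product"] - merged[f"{var}_field"]
        monthly = diff.groupby(merged["month"]).mean().reindex(range(1, 13))
        entry = {
            "bias": float(diff.mean()),
            "rmse": float(np.sqrt((diff ** 2).mean())),
            "monthly_profile": monthly,
        }
        if inputs is not None:
            swapped = inputs.forcing_field.copy()
            prod = series_product[["year", "month", var]].rename(columns={var: "_swap"})
            swapped = swapped.merge(prod, on=["year", "month"], how="inner")
            swapped[var] = swapped["_swap"]
            swapped = swapped.drop(columns=["_swap"])
            alt = SiteInputs(
                site=inputs.site, forcing_field=swapped,
                forcing_product=inputs.forcing_product,
                fapar_field=inputs.fapar_field,
                fapar_satellite=inputs.fapar_satellite,
                cwm=inputs.cwm, growth_tc=inputs.growth_tc,
                params=inputs.params, biome=inputs.biome,
            )
            entry["gpp_sensitivity"] = run_experiment("Pmodel_Pf", alt) - baseline
        report[var] = entry
    return report


def attribute_site(forcing_field: pd.DataFrame, forcing_product: pd.DataFrame,
                   gas_exchange: pd.DataFrame, fapar_insitu: pd.DataFrame,
                   fapar_satellite: pd.DataFrame, gpp_components: pd.DataFrame,
                   site: str, params: pc.PhotoParams | None = None,
                   biome: BiomeLookupParams | None = None,
                   policy: str = "exclude_significant",
                   product_gpp: float | None = None,
                   years: tuple[int, int] | None = None) -> dict:
    """End-to-end attribution for one site from raw input tables.

    Runs trait inversion -> community mean, fAPAR filtering ->
    climatologies, biometric aggregation, the five GPP experiments, and
    the ledger decomposition. ``product_gpp`` overrides the lookup-table
    emulator with an externally supplied product value (replication
    mode); the returned dict records which was used.
    """
    params = params or pc.PhotoParams()
    biome = biome or BiomeLookupParams()
    growth_tc = tr.growth_temperature(forcing_field)
    trait_list, trait_log = tr.derive_traits(gas_exchange, phi0=params.phi0,
                                             growth_tc=growth_tc)
    cwm = tr.community_weighted_mean(trait_list)

    sat_kept, _removed = fp.filter_observations(fapar_satellite, policy)
    clim_field = fp.monthly_climatology(fapar_insitu, years)
    clim_sat = fp.monthly_climatology(sat_kept, years)

    plots = bm.plots_from_components_table(gpp_components)
    site_gpp = bm.site_mean(plots)

    inputs = SiteInputs(
        site=site, forcing_field=forcing_field, forcing_product=forcing_product,
        fapar_field=clim_field, fapar_satellite=clim_sat,
        cwm=cwm, growth_tc=growth_tc, params=params, biome=biome,
    )
    gpps = run_all_experiments(inputs)
    product = product_gpp if product_gpp is not None else gpps["product"]
    ledger = decompose(site_gpp.gpp, gpps["Pmodel_PfL"], gpps["Pmodel_Pf"],
                       gpps["Pmodel_P"], product, site=site)
    return {
        "site": site,
        "ledger": ledger,
        "experiments": gpps,
        "biometric": site_gpp,
        "cwm": cwm,
        "trait_log": trait_log,
        "ppfd_term": gpps["Pmodel_P"] - gpps["Pmodel_null"],
        "product_source": "external" if product_gpp is not None else "lookup_emulator",
        "inputs": inputs,
    }
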