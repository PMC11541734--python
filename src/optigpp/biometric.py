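"""Bottom-up (biometric) GPP from field-measured components.

Plot-level GPP is the sum of independently measured components (canopy
productivity from litterfall traps, stem respiration from chamber
measurements, fine-root productivity, ...), each with a measurement
uncertainty. Uncertainties combine in quadrature (independent errors);
an optional covariance matrix relaxes the independence assumption. Site
GPP is the unweighted mean across plots, and its reported uncertainty is
the mean of plot measurement uncertainties — deliberately a measurement
error, not a spatial standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GppComponent",
    "PlotGpp",
    "sum_components",
    "site_mean",
    "plots_from_components_table",
]


@dataclass(frozen=True)
class GppComponent:
    """One GPP component, MgC ha-1 yr-1."""

    name: str
    value: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class PlotGpp:
    plot: str
    site: str
    gpp: float
    sigma: float


def sum_components(components: list[GppComponent], plot: str = "", site: str = "",
                   cov: np.ndarray | None = None) -> PlotGpp:
    """Plot GPP = sum of components; sigma by quadrature (or full covariance).

    With cov given (component ordering matching the list), the variance is
    1' C 1; the diagonal of cov then replaces the per-component sigmas.
    """
    if not components:
        raise ValueError("sum_components needs a non-empty component list")
    total = sum(comp.value for comp in components)
    if cov is not None:
        cov = np.asarray(cov, dtype=float)
        n = len(components)
        if cov.shape != (n, n):
            raise ValueError(f"covariance must be {n}x{n}, got {cov.shape}")
        var = float(np.ones(n) @ cov @ np.ones(n))
    else:
        var = sum(comp.sigma ** 2 for comp in components)
    return PlotGpp(plot=plot, site=site, gpp=total, sigma=math.sqrt(var))


def site_mean(plots: list[PlotGpp]) -> PlotGpp:
    """Unweighted mean across plots; uncertainty = mean plot sigma (measurement error)."""
    if not plots:
        raise ValueError("site_mean needs a non-empty plot list")
    sites = {p.site for p in plots}
    if len(sites) > 1:
        raise ValueError(f"plots span multiple sites: {sorted(sites)}")
    gpp = sum(p.gpp for p in plots) / len(plots)
    sigma = sum(p.sigma for p in plots) / len(plots)
    return PlotGpp(plot="site_mean", site=plots[0].site, gpp=gpp, sigma=sigma)


def plots_from_components_table(df: pd.DataFrame) -> list[PlotGpp]:
    """Aggregate a (site, plot, component, value, sigma) table to plot GPPs."""
    plots = []
    for (site, plot), grp in df.groupby(["site", "plot"], sort=True):
        comps = [GppComponent(str(r["component"]), float(r["value"]), float(r["sigma"]))
                 for _, r in grp.iterrows()]
        plots.append(sum_components(comps, plot=str(plot), site=str(site)))
    return plots
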