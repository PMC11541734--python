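"""ci/ca from leaf carbon-isotope composition.

Photosynthetic discrimination against 13C is computed from leaf and air
delta-13C, then inverted with the simple two-endpoint fractionation model
Delta = a + (b - a) * ci/ca, where a is the fractionation during
diffusion through stomata (~4.4 permil) and b during carboxylation
(~27 permil). The resulting chi is an independent, field-based check on
the optimality prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "IsotopeRecord",
    "discrimination",
    "chi_from_discrimination",
    "derive_chi_table",
    "A_DIFFUSION",
    "B_CARBOXYLATION",
    "DELTA13C_AIR_DEFAULT",
]

#: Fractionation by diffusion in air, permil.
A_DIFFUSION = 4.4
#: Fractionation by Rubisco carboxylation, permil.
B_CARBOXYLATION = 27.0
#: Default atmospheric delta-13C vs VPDB, permil.
DELTA13C_AIR_DEFAULT = -8.0


@dataclass(frozen=True)
class IsotopeRecord:
    delta13c_leaf: float
    delta13c_air: float
    big_delta: float
    chi_isotope: float
    flagged: bool = False


def discrimination(delta_leaf: float, delta_air: float = DELTA13C_AIR_DEFAULT) -> float:
    """Discrimination Delta-13C (permil) = (d_air - d_leaf) / (1 + d_leaf/1000)."""
    if delta_leaf <= -1000.0:
        raise ValueError("delta_leaf = -1000 permil makes discrimination undefined")
    return (delta_air - delta_leaf) / (1.0 + delta_leaf / 1000.0)


def chi_from_discrimination(big_delta: float, a: float = A_DIFFUSION,
                            b: float = B_CARBOXYLATION) -> tuple[float, bool]:
    """chi = (Delta - a)/(b - a); values outside (0, 1) are clamped and flagged."""
    if b == a:
        raise ValueError("b must differ from a")
    if b < a:
        raise ValueError("b must exceed a")
    chi = (big_delta - a) / (b - a)
    flagged = not 0.0 <= chi <= 1.0
    return min(1.0, max(0.0, chi)), flagged


def derive_chi_table(df: pd.DataFrame, a: float = A_DIFFUSION,
                     b: float = B_CARBOXYLATION,
                     delta_air_default: float = DELTA13C_AIR_DEFAULT) -> pd.DataFrame:
    """Per-row isotope-derived chi from a (species, plot, delta13c_leaf[, delta13c_air]) table."""
    out = df.copy()
    air = out["delta13c_air"] if "delta13c_air" in out.columns else delta_air_default
    if not isinstance(air, pd.Series):
        air = pd.Series(air, index=out.index, dtype=float)
    air = air.fillna(delta_air_default)
    rows = []
    for leaf, d_air in zip(out["delta13c_leaf"].astype(float), air.astype(float)):
        big = discrimination(leaf, d_air)
        chi, flagged = chi_from_discrimination(big, a, b)
        rows.append((d_air, big, chi, flagged))
    out["delta13c_air"] = [r[0] for r in rows]
    out["big_delta"] = [r[1] for r in rows]
    out["chi_isotope"] = [r[2] for r in rows]
    out["flagged"] = [r[3] for r in rows]
    return out
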