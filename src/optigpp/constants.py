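"""Physical and biochemical constants used across the package.

Kinetic reference values follow the Bernacchi-type Arrhenius
parameterisation adopted by the standard optimality-based light-use-
efficiency model: 25 degC reference values of the photorespiratory
compensation point (Gamma*), the Michaelis constants for CO2 and O2, and
their activation energies. They are collected here in one table so the
whole package shares a single, versionable source of truth; the table can
be dumped to / loaded from JSON for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.3145

#: Reference (standard sea-level) atmospheric pressure, Pa.
P_REF = 101325.0

#: Reference temperature for all kinetic constants, degC.
TC_REF = 25.0

#: Molar mass of carbon, g mol-1.
MC_CARBON = 12.0107

#: Atmospheric O2 mole fraction, unitless.
O2_FRAC = 0.2095

#: Photorespiratory compensation point at 25 degC and P_REF, Pa.
GAMMASTAR25 = 4.332

#: Michaelis constant of Rubisco for CO2 at 25 degC, Pa.
KC25 = 39.97

#: Michaelis constant of Rubisco for O2 at 25 degC, Pa.
KO25 = 27480.0

#: Activation energies, J mol-1.
DHA_GAMMASTAR = 37830.0
DHA_KC = 79430.0
DHA_KO = 36380.0

#: Activation energies for trait temperature normalisation, J mol-1.
#: Vcmax and Jmax values are field-community medians widely used for
#: temperature adjustment of C3 photosynthetic capacity; dark respiration
#: uses a lower energy reflecting its weaker temperature response over
#: the tropical canopy range.
DHA_VCMAX = 65330.0
DHA_JMAX = 43900.0
DHA_RD = 30000.0

#: PPFD from shortwave radiation, umol photons per J of SW (configurable
#: at call sites; this is the conventional default).
PPFD_PER_SW_J = 2.04

#: umol photons per J of PAR, used to convert lookup-table maximum LUE
#: from gC MJ-1 (APAR) to gC mol-1 photons.
PPFD_PER_PAR_J = 4.6

#: gC m-2 yr-1 -> MgC ha-1 yr-1 (exact).
GC_M2_TO_MGC_HA = 0.01

CONSTANTS_TABLE = {
    "r_gas_J_mol_K": R_GAS,
    "p_ref_Pa": P_REF,
    "tc_ref_C": TC_REF,
    "mc_carbon_g_mol": MC_CARBON,
    "o2_frac": O2_FRAC,
    "gammastar25_Pa": GAMMASTAR25,
    "kc25_Pa": KC25,
    "ko25_Pa": KO25,
    "dha_gammastar_J_mol": DHA_GAMMASTAR,
    "dha_kc_J_mol": DHA_KC,
    "dha_ko_J_mol": DHA_KO,
    "dha_vcmax_J_mol": DHA_VCMAX,
    "dha_jmax_J_mol": DHA_JMAX,
    "dha_rd_J_mol": DHA_RD,
    "ppfd_per_sw_J_umol": PPFD_PER_SW_J,
    "ppfd_per_par_J_umol": PPFD_PER_PAR_J,
    "gc_m2_to_mgc_ha": GC_M2_TO_MGC_HA,
    "version": 1,
}


def dump_constants(path: str | Path) -> None:
    """Write the constants table as versioned JSON."""
    Path(path).write_text(json.dumps(CONSTANTS_TABLE, indent=2, sort_keys=True))


def load_constants(path: str | Path) -> dict:
    """Read a constants table previously written by :func:`dump_constants`."""
    return json.loads(Path(path).read_text())
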