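"""Physical constants and per-species bookkeeping tables.

Two distinct electron conventions coexist on purpose:

* ``electron_equiv`` — electrons per mole under full-oxidation bookkeeping
  (xylose 20, ethanol 12, acetate 8, H2 2, biomass C5H7O2N 20).  Used by the
  electron-conversion-efficiency (ECE) accounting.
* ``coulomb_b`` — the *net* electrons transferred when one mole of the product
  is formed from 0.6 mol xylose (ethanol 3.4, acetate 0.6, H2 2).  Used only by
  the metabolite-coulomb equation C = F·b·V·Δn.

They are not interchangeable; each equation pulls its own column.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

#: Faraday constant, C per mol electrons.
FARADAY = 96_485.0

#: Molar gas volume used for H2 volume <-> mole conversion, L mol^-1.
MOLAR_GAS_VOLUME = 24.03

#: Molar mass of xylose, g mol^-1.
XYLOSE_MOLAR_MASS = 150.13

#: Molar mass of biomass on the C5H7O2N convention, g mol^-1.
BIOMASS_MOLAR_MASS = 113.11


@dataclass(frozen=True)
class SpeciesConstants:
    """Immutable per-species constants for the balance equations."""

    species: str
    carbon_atoms: int
    electron_equiv: int
    molar_mass: float
    coulomb_b: float | None = None  # None: species has no net-coulomb convention


SPECIES = MappingProxyType(
    {
        "xylose": SpeciesConstants("xylose", 5, 20, XYLOSE_MOLAR_MASS, coulomb_b=20.0),
        "ethanol": SpeciesConstants("ethanol", 2, 12, 46.07, coulomb_b=3.4),
        "acetate": SpeciesConstants("acetate", 2, 8, 60.05, coulomb_b=0.6),
        "hydrogen": SpeciesConstants("hydrogen", 0, 2, 2.016, coulomb_b=2.0),
        "biomass": SpeciesConstants("biomass", 5, 20, BIOMASS_MOLAR_MASS),
    }
)


def species_constants(name: str) -> SpeciesConstants:
    """Look up the constants row for *name*, raising on unknown species."""
    try:
        return SPECIES[name]
    except KeyError:
        raise KeyError(f"unknown species {name!r}; known: {sorted(SPECIES)}") from None
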