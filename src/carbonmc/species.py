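"""Particle species and target-element registries.

The fragment species set is the fixed list of isotopes with non-negligible
production cross-section in carbon fragmentation at therapeutic energies:
neutrons plus all charged isotopes from hydrogen up to carbon-12.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError


@dataclass(frozen=True)
class FragmentSpecies:
    name: str
    Z: int  # charge number
    A: int  # mass number

    @property
    def charged(self) -> bool:
        return self.Z > 0


#: The 18 species the fragmentation model can emit, keyed by name.
SPECIES: dict[str, FragmentSpecies] = {
    s.name: s
    for s in [
        FragmentSpecies("n", 0, 1),
        FragmentSpecies("1H", 1, 1),
        FragmentSpecies("2H", 1, 2),
        FragmentSpecies("3H", 1, 3),
        FragmentSpecies("3He", 2, 3),
        FragmentSpecies("4He", 2, 4),
        FragmentSpecies("6He", 2, 6),
        FragmentSpecies("6Li", 3, 6),
        FragmentSpecies("7Li", 3, 7),
        FragmentSpecies("7Be", 4, 7),
        FragmentSpecies("9Be", 4, 9),
        FragmentSpecies("10Be", 4, 10),
        FragmentSpecies("8B", 5, 8),
        FragmentSpecies("10B", 5, 10),
        FragmentSpecies("11B", 5, 11),
        FragmentSpecies("10C", 6, 10),
        FragmentSpecies("11C", 6, 11),
        FragmentSpecies("12C", 6, 12),
    ]
}

#: Species whose energy-angle law is the full two-component mixture
#: (projectile and target contributions overlap and cannot be separated).
HYDROGEN_LIKE = frozenset({"n", "1H", "2H", "3H"})


@dataclass(frozen=True)
class Element:
    """Target element: atomic data plus radiation length and mean excitation
    energy used by the continuous-process models."""

    symbol: str
    Z: int
    A: float        # standard atomic weight, g/mol
    I_eV: float     # mean excitation energy
    X0: float       # radiation length, g/cm^2


ELEMENTS: dict[str, Element] = {
    e.symbol: e
    for e in [
        Element("H", 1, 1.008, 19.2, 63.04),
        Element("C", 6, 12.011, 78.0, 42.70),
        Element("N", 7, 14.007, 82.0, 37.99),
        Element("O", 8, 15.999, 95.0, 34.24),
        Element("Al", 13, 26.982, 166.0, 24.01),
        Element("P", 15, 30.974, 173.0, 21.21),
        Element("Ca", 20, 40.078, 191.0, 16.14),
        Element("Ti", 22, 47.867, 233.0, 16.16),
    ]
}


def get_species(name: str) -> FragmentSpecies:
    try:
        return SPECIES[name]
    except KeyError:
        raise ConfigurationError(f"unknown species {name!r}") from None


def get_element(symbol: str) -> Element:
    try:
        return ELEMENTS[symbol]
    except KeyError:
        raise ConfigurationError(f"unknown element {symbol!r}") from None
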