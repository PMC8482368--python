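"""Atomic constants and natural isotope abundances.

Monoisotopic masses are IUPAC/CODATA values hard-coded to >= 6 decimals. All
mass arithmetic in the package flows through an :class:`AtomTable`, so custom
abundance sets (or exotic calibrations) can be injected everywhere a default
table is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

#: Monoisotopic masses (Da). Plain element symbols denote the lightest
#: (principal) isotope; prefixed symbols denote specific heavy isotopes.
MONOISOTOPIC_MASS: Mapping[str, float] = MappingProxyType({
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "2H": 2.0141017778,
    "13C": 13.0033548378,
    "15N": 15.0001088982,
    "17O": 16.99913170,
    "18O": 17.99916104,
    "34S": 33.96786690,
})

PROTON_MASS = 1.00727646688  # Da, mass of H minus electron
WATER_MASS = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]

#: Default natural abundance of the minor isotopes, as fractions per atom.
#: The principal isotope takes the remainder.
NATURAL_ABUNDANCE: Mapping[str, Mapping[str, float]] = MappingProxyType({
    "C": MappingProxyType({"13C": 0.0107}),
    "H": MappingProxyType({"2H": 0.000115}),
    "N": MappingProxyType({"15N": 0.00364}),
    "O": MappingProxyType({"17O": 0.00038, "18O": 0.00205}),
    "S": MappingProxyType({"34S": 0.0429}),
})


@dataclass(frozen=True)
class AtomTable:
    """Monoisotopic masses and per-element natural isotope abundances.

    Parameters
    ----------
    masses :
        Symbol -> monoisotopic mass (Da). Must cover every element and minor
        isotope referenced by ``abundances``.
    abundances :
        Element -> {minor isotope symbol -> natural fraction}. The principal
        isotope's fraction is ``1 - sum(minor fractions)`` and must be
        positive; total per element is 1 by construction.
    proton :
        Proton mass (Da) used for m/z conversion.
    """

    masses: Mapping[str, float] = field(default_factory=lambda: MONOISOTOPIC_MASS)
    abundances: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: NATURAL_ABUNDANCE)
    proton: float = PROTON_MASS

    def __post_init__(self) -> None:
        for sym, m in self.masses.items():
            if m <= 0:
                raise ValueError(f"non-positive mass for {sym!r}: {m}")
        if self.proton <= 0:
            raise ValueError("proton mass must be positive")
        for elem, minors in self.abundances.items():
            if elem not in self.masses:
                raise ValueError(f"abundances given for unknown element {elem!r}")
            total_minor = 0.0
            for iso, frac in minors.items():
                if iso not in self.masses:
                    raise ValueError(f"unknown isotope symbol {iso!r}")
                if not 0.0 <= frac < 1.0:
                    raise ValueError(f"abundance of {iso!r} out of [0, 1): {frac}")
                total_minor += frac
            if total_minor >= 1.0 - 1e-9:
                raise ValueError(
                    f"minor-isotope fractions of {elem!r} sum to {total_minor}, "
                    "leaving no room for the principal isotope"
                )

    def mass(self, symbol: str) -> float:
        try:
            return self.masses[symbol]
        except KeyError:
            raise KeyError(f"no mass for symbol {symbol!r}") from None

    def minor_isotopes(self, element: str) -> list[tuple[str, float, float]]:
        """Return ``(isotope, mass_shift_Da, abundance)`` for each minor isotope."""
        base = self.mass(element)
        return [
            (iso, self.mass(iso) - base, frac)
            for iso, frac in self.abundances.get(element, {}).items()
        ]


#: Shared default table.
DEFAULT_ATOMS = AtomTable()
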