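"""Isotopologue enumeration and exact mass arithmetic for multi-lysine peptides.

The combined metabolic/chemical labeling scheme puts one of three acetyl
variants on every modifiable lysine of a fully derivatized tryptic peptide:

* ``LIGHT``  — endogenous acetyl from unlabeled glucose (12C2, H3 methyl),
* ``HEAVY``  — endogenous acetyl from [U-13C]-glucose (13C2, H3 methyl),
* ``CHEM``   — chemical acetyl from 13C4,D6-acetic anhydride (13C2, D3 methyl).

A peptide with *n* modifiable lysines therefore occurs as 3**n isotopologues.
This module enumerates them, computes neutral masses, precursor and b/y
fragment m/z, elemental formulas with labeled atoms tracked separately from
the unlabeled backbone, and the grouping of species that are isobaric at the
MS1 level.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .constants import DEFAULT_ATOMS, WATER_MASS, AtomTable

__all__ = [
    "AcetylLabel",
    "Formula",
    "PeptideSpec",
    "Isotopologue",
    "IsobaricGroup",
    "FragmentIon",
    "RESIDUE_FORMULAS",
    "peptide_formula",
    "peptide_monoisotopic_mass",
    "enumerate_isotopologues",
    "isotopologue_mz",
    "fragment_mz",
    "group_isobaric",
    "elemental_formula",
    "roman",
]

#: Elemental composition of the 20 standard amino acid residues (no water).
RESIDUE_FORMULAS: Mapping[str, Mapping[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

_LABEL_SYMBOLS = {"13C", "2H", "15N", "18O"}  # symbols treated as *labeled* atoms


@dataclass(frozen=True)
class Formula:
    """Elemental formula keeping isotopically labeled atoms separate.

    ``counts`` maps plain element symbols (unlabeled atoms, subject to natural
    isotope variation) and heavy-isotope symbols such as ``"13C"`` (labeled
    atoms, fixed) to atom counts. Intermediate arithmetic may produce negative
    counts (e.g. the amine hydrogen displaced by an acetyl group); a complete
    molecule must have non-negative counts everywhere.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", MappingProxy({k: int(v) for k, v in self.counts.items() if v != 0})
        )

    def __add__(self, other: "Formula") -> "Formula":
        c = Counter(self.counts)
        c.update(other.counts)
        return Formula(c)

    def __mul__(self, n: int) -> "Formula":
        return Formula({k: v * n for k, v in self.counts.items()})

    __rmul__ = __mul__

    @property
    def unlabeled(self) -> dict[str, int]:
        return {k: v for k, v in self.counts.items() if k not in _LABEL_SYMBOLS}

    @property
    def labeled(self) -> dict[str, int]:
        return {k: v for k, v in self.counts.items() if k in _LABEL_SYMBOLS}

    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def mass(self, atoms: AtomTable = DEFAULT_ATOMS) -> float:
        return sum(n * atoms.mass(sym) for sym, n in self.counts.items())

    def validate_molecule(self) -> "Formula":
        bad = {k: v for k, v in self.counts.items() if v < 0}
        if bad:
            raise ValueError(f"negative atom counts in formula: {bad}")
        return self

    def __str__(self) -> str:  # e.g. C44H76N14O14 + [13C]4[2H]6
        plain = "".join(
            f"{k}{v}" for k, v in sorted(self.unlabeled.items())
        )
        lab = "".join(f"[{k}]{v}" for k, v in sorted(self.labeled.items()))
        return plain + (f" + {lab}" if lab else "")


# Small immutable-mapping helper so Formula stays hashable-by-identity safe.
class MappingProxy(dict):
    def __setitem__(self, *a):  # pragma: no cover - defensive
        raise TypeError("Formula counts are immutable")


class AcetylLabel(Enum):
    """The three acetyl label states, ordered LIGHT < HEAVY < CHEM."""

    LIGHT = 0  # 12C2 H3 acetyl, endogenous before the medium switch
    HEAVY = 1  # 13C2 H3 acetyl, endogenous after the switch to [U-13C]-Glc
    CHEM = 2   # 13C2 D3 acetyl, chemical derivatization of unmodified lysine

    @property
    def delta_formula(self) -> Formula:
        """Net elemental addition of this acetyl to a lysine epsilon-amine."""
        if self is AcetylLabel.LIGHT:
            return Formula({"C": 2, "H": 2, "O": 1})
        if self is AcetylLabel.HEAVY:
            return Formula({"13C": 2, "H": 2, "O": 1})
        # CHEM: 13C2 carbonyl+methyl carbons, D3 methyl; one ordinary amine H lost
        return Formula({"13C": 2, "2H": 3, "H": -1, "O": 1})

    def delta_mass(self, atoms: AtomTable = DEFAULT_ATOMS) -> float:
        return self.delta_formula.mass(atoms)

    @property
    def code(self) -> str:
        return {"LIGHT": "L", "HEAVY": "H", "CHEM": "C"}[self.name]

    def __lt__(self, other: "AcetylLabel") -> bool:
        if not isinstance(other, AcetylLabel):
            return NotImplemented
        return self.value < other.value


def label_mass_delta(label: AcetylLabel, atoms: AtomTable = DEFAULT_ATOMS) -> float:
    """Mass added to the peptide by one acetyl of the given label state (Da)."""
    return label.delta_mass(atoms)


@dataclass(frozen=True)
class PeptideSpec:
    """A tryptic peptide with indexed modifiable lysines.

    ``sites`` are 0-based indices into ``sequence``; display names use
    protein residue numbering via ``residue_offset`` (residue number =
    offset + index), e.g. H3(18-26) K18/K23.
    """

    name: str
    sequence: str
    sites: tuple[int, ...]
    residue_offset: int = 1
    nterm_acetyl: bool = False
    fixed_mods: tuple[tuple[str, int, Mapping[str, int]], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for pos, aa in enumerate(self.sequence):
            if aa not in RESIDUE_FORMULAS:
                raise ValueError(f"unknown residue {aa!r} at position {pos} of {self.name!r}")
        object.__setattr__(self, "sites", tuple(self.sites))
        if list(self.sites) != sorted(set(self.sites)):
            raise ValueError("site indices must be strictly increasing and unique")
        for i in self.sites:
            if not 0 <= i < len(self.sequence):
                raise ValueError(f"site index {i} outside sequence")
            if self.sequence[i] != "K":
                raise ValueError(f"site index {i} is {self.sequence[i]!r}, not a lysine")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_names(self) -> tuple[str, ...]:
        return tuple(f"K{self.residue_offset + i}" for i in self.sites)

    def site_name(self, site_pos: int) -> str:
        """Name of the ``site_pos``-th modifiable lysine (0-based)."""
        return self.site_names[site_pos]


def peptide_formula(spec: PeptideSpec) -> Formula:
    """Elemental formula of the unmodified peptide (free amine, + water)."""
    c: Counter = Counter({"H": 2, "O": 1})  # water
    for aa in spec.sequence:
        c.update(RESIDUE_FORMULAS[aa])
    f = Formula(c)
    for _name, _site, delta in spec.fixed_mods:
        f = f + Formula(delta)
    if spec.nterm_acetyl:
        f = f + AcetylLabel.CHEM.delta_formula
    return f.validate_molecule()


def peptide_monoisotopic_mass(spec: PeptideSpec, atoms: AtomTable = DEFAULT_ATOMS) -> float:
    """Neutral monoisotopic mass of the peptide without site acetyls (Da)."""
    return peptide_formula(spec).mass(atoms)


def roman(n: int) -> str:
    """Roman numeral for n >= 1 (display ids follow the figure convention)."""
    if n < 1:
        raise ValueError("roman numerals start at 1")
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
            (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for v, s in vals:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


@dataclass(frozen=True)
class Isotopologue:
    """One per-site acetyl label assignment of a fully acetylated peptide."""

    peptide: PeptideSpec
    labels: tuple[AcetylLabel, ...]
    display_id: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != self.peptide.n_sites:
            raise ValueError("one label per modifiable site required")
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def label_codes(self) -> str:
        return "".join(l.code for l in self.labels)

    @property
    def state_id(self) -> str:
        """In vivo state string: CHEM site = unmodified (U), else L/H."""
        return "".join({"L": "L", "H": "H", "C": "U"}[l.code] for l in self.labels)

    def formula(self) -> Formula:
        f = peptide_formula(self.peptide)
        for lab in self.labels:
            f = f + lab.delta_formula
        return f.validate_molecule()

    def mass(self, atoms: AtomTable = DEFAULT_ATOMS) -> float:
        return peptide_monoisotopic_mass(self.peptide, atoms) + sum(
            lab.delta_mass(atoms) for lab in self.labels
        )

    def mz(self, charge: int, atoms: AtomTable = DEFAULT_ATOMS) -> float:
        return isotopologue_mz(self, charge, atoms)

    def describe(self) -> str:
        parts = [
            f"{name}ac[{lab.name}]"
            for name, lab in zip(self.peptide.site_names, self.labels)
        ]
        return f"{self.display_id or self.label_codes}: " + " ".join(parts)


def _display_order_key(labels: Sequence[AcetylLabel]) -> tuple:
    """Sort key reproducing the figure-style roman numbering.

    Species are numbered by increasing number of heavy (13C2H3) acetyls, then
    by increasing number of endogenous acetyls, ties broken by putting the
    heavy, then the light acetyl on the earlier site first.
    """
    n_heavy = sum(l is AcetylLabel.HEAVY for l in labels)
    n_endo = sum(l is not AcetylLabel.CHEM for l in labels)
    rank = {AcetylLabel.HEAVY: 0, AcetylLabel.LIGHT: 1, AcetylLabel.CHEM: 2}
    return (n_heavy, n_endo, tuple(rank[l] for l in labels))


def enumerate_isotopologues(spec: PeptideSpec) -> list[Isotopologue]:
    """All 3**n isotopologues in deterministic lexicographic order.

    The list order is lexicographic over sites with LIGHT < HEAVY < CHEM;
    display ids (roman numerals) follow the conventional figure ordering
    (nonacetylated species first, fully heavy-labeled last).
    """
    order = (AcetylLabel.LIGHT, AcetylLabel.HEAVY, AcetylLabel.CHEM)
    combos = list(itertools.product(order, repeat=spec.n_sites))
    by_display = sorted(combos, key=_display_order_key)
    ids = {labels: roman(i + 1) for i, labels in enumerate(by_display)}
    return [Isotopologue(spec, labels, ids[labels]) for labels in combos]


def isotopologue_mz(
    iso: Isotopologue, charge: int, atoms: AtomTable = DEFAULT_ATOMS
) -> float:
    """Precursor m/z at the given positive charge state."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (iso.mass(atoms) + charge * atoms.proton) / charge


@dataclass(frozen=True)
class FragmentIon:
    """A b- or y-series backbone fragment of one isotopologue."""

    series: str
    index: int
    charge: int
    site_positions: tuple[int, ...]  # 0-based positions of contained acetyl sites
    mz: float
    parent_id: str

    @property
    def ion_name(self) -> str:
        return f"{self.series}{self.index}" + (f"z{self.charge}" if self.charge != 1 else "")


def fragment_mz(
    iso: Isotopologue,
    series: str,
    index: int,
    charge: int = 1,
    atoms: AtomTable = DEFAULT_ATOMS,
) -> FragmentIon:
    """Theoretical m/z of the b_index or y_index ion of an isotopologue.

    b ions carry the first ``index`` residues (neutral = residue sum); y ions
    carry the last ``index`` residues plus water. Acetyl deltas of the sites
    contained in the fragment are included.
    """
    spec = iso.peptide
    n = len(spec.sequence)
    if series not in ("b", "y"):
        raise ValueError(f"series must be 'b' or 'y', got {series!r}")
    if not 1 <= index < n:
        raise ValueError(f"fragment index {index} out of range 1..{n - 1}")
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")

    if series == "b":
        residues = spec.sequence[:index]
        contained = [i for i in spec.sites if i < index]
        neutral = 0.0
        if spec.nterm_acetyl:
            neutral += AcetylLabel.CHEM.delta_mass(atoms)
    else:
        residues = spec.sequence[n - index:]
        contained = [i for i in spec.sites if i >= n - index]
        neutral = WATER_MASS

    neutral += sum(Formula(RESIDUE_FORMULAS[aa]).mass(atoms) for aa in residues)
    for pos, lab in zip(spec.sites, iso.labels):
        if pos in contained:
            neutral += lab.delta_mass(atoms)
    for _name, site, delta in spec.fixed_mods:
        if (series == "b" and site < index) or (series == "y" and site >= n - index):
            neutral += Formula(delta).mass(atoms)

    mz = (neutral + charge * atoms.proton) / charge
    return FragmentIon(series, index, charge, tuple(contained), mz, iso.display_id)


@dataclass(frozen=True)
class IsobaricGroup:
    """Isotopologues unresolvable at MS1 within a mass tolerance."""

    members: tuple[Isotopologue, ...]
    charge: int
    mz: float  # representative (mean member) m/z
    group_id: str = field(default="")

    def __post_init__(self) -> None:
        if not self.group_id:
            object.__setattr__(
                self, "group_id", "+".join(m.display_id for m in self.members)
            )

    @property
    def needs_ms2(self) -> bool:
        return len(self.members) > 1


def group_isobaric(
    species: Iterable[Isotopologue],
    charge: int = 2,
    tol: float = 0.005,
    atoms: AtomTable = DEFAULT_ATOMS,
) -> list[IsobaricGroup]:
    """Partition isotopologues into MS1-isobaric groups.

    Single-linkage clustering on precursor m/z: a gap larger than ``tol``
    (Da/charge) starts a new group. With the symmetric three-state label
    chemistry the group count equals the number of label multisets,
    C(n+2, 2) for n sites.
    """
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    ordered = sorted(species, key=lambda s: s.mz(charge, atoms))
    groups: list[list[Isotopologue]] = []
    last_mz = None
    for iso in ordered:
        mz = iso.mz(charge, atoms)
        if last_mz is None or mz - last_mz > tol:
            groups.append([iso])
        else:
            groups[-1].append(iso)
        last_mz = mz
    out = []
    for g in groups:
        members = tuple(sorted(g, key=lambda s: _display_order_key(s.labels)))
        mzs = [m.mz(charge, atoms) for m in members]
        out.append(IsobaricGroup(members, charge, sum(mzs) / len(mzs)))
    return out


def elemental_formula(iso: Isotopologue) -> Formula:
    """Elemental formula with labeled 13C/2H counted separately (alias)."""
    return iso.formula()
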