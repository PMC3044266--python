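"""Mass chemistry and in-silico digestion.

Residue mass tables, peptide and disulfide-structure mass arithmetic,
proteolytic digestion, cysteine-containing-peptide (CCP) extraction and
connectivity-pattern counting.  All masses are neutral daltons; the
monoisotopic scale is the default throughout.

A disulfide (S-S) bond forms by oxidation of two cysteine thiols and
removes two hydrogen atoms, so the mass of a bonded structure is the sum
of its peptide masses minus ``2 * HYDROGEN`` per bond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Sequence

from pyteomics import mass as _ptmass
from pyteomics import parser as _ptparser

# ---------------------------------------------------------------------------
# Constants (monoisotopic, Da)
# ---------------------------------------------------------------------------

WATER = 18.0105646863
PROTON = 1.00727646677
HYDROGEN = 1.0078250319
CO = 27.9949146221
NH3 = 17.0265491015

#: Mass removed per disulfide bond (two hydrogens).
SS_BOND_DELTA = 2.0 * HYDROGEN

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def _average_residue_masses() -> dict[str, float]:
    return {
        aa: _ptmass.calculate_mass(composition=_ptmass.std_aa_comp[aa], average=True)
        for aa in _STANDARD_RESIDUES
    }


@dataclass(frozen=True)
class ResidueMassTable:
    """Residue -> neutral residue mass, on both mass scales.

    The default table is built from the pyteomics standard amino-acid
    compositions.  ``offsets`` holds fixed per-residue modification masses
    (e.g. carbamidomethylation of cysteine) added on both scales.
    """

    monoisotopic: dict[str, float]
    average: dict[str, float]
    offsets: dict[str, float] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ResidueMassTable":
        mono = {aa: _ptmass.std_aa_mass[aa] for aa in _STANDARD_RESIDUES}
        return cls(monoisotopic=mono, average=_average_residue_masses())

    @classmethod
    def from_file(cls, path) -> "ResidueMassTable":
        """Override monoisotopic masses from a text file of ``residue mass`` lines."""
        table = cls.default()
        mono = dict(table.monoisotopic)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace("=", " ").split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 'residue mass', got {line!r}")
                mono[parts[0]] = float(parts[1])
        return cls(monoisotopic=mono, average=dict(table.average))

    def with_offsets(self, offsets: dict[str, float]) -> "ResidueMassTable":
        return replace(self, offsets=dict(offsets))

    def residue_mass(self, residue: str, scale: str = "monoisotopic") -> float:
        if scale not in ("monoisotopic", "average"):
            raise ValueError(f"unknown mass scale {scale!r}")
        base = self.monoisotopic if scale == "monoisotopic" else self.average
        if residue not in base:
            raise ValueError(f"unknown residue {residue!r}")
        return base[residue] + self.offsets.get(residue, 0.0)

    @property
    def aa_max(self) -> float:
        return max(self.monoisotopic.values())

    @property
    def aa_min(self) -> float:
        return min(self.monoisotopic.values())

    @property
    def aa_average(self) -> float:
        return sum(self.monoisotopic.values()) / len(self.monoisotopic)


_DEFAULT_TABLE = ResidueMassTable.default()


def default_table() -> ResidueMassTable:
    return _DEFAULT_TABLE


# ---------------------------------------------------------------------------
# Peptides
# ---------------------------------------------------------------------------


def peptide_mass(
    sequence: str,
    scale: str = "monoisotopic",
    table: ResidueMassTable | None = None,
) -> float:
    """Neutral mass of a peptide: sum of residue masses plus one water."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    table = table or _DEFAULT_TABLE
    return sum(table.residue_mass(aa, scale) for aa in sequence) + WATER


@dataclass(frozen=True)
class Peptide:
    """A digested (or synthetic mass-only) peptide.

    ``start``/``end`` are 0-based half-open indices into the parent
    protein.  Mass-only peptides (mass-list mode, where only CCP mass
    values are known) carry ``sequence=None`` and placeholder cysteine
    offsets; they support first-stage matching but not fragmentation.
    """

    sequence: str | None
    start: int
    end: int
    mass: float
    cys_positions: tuple[int, ...]
    label: str | None = None

    @classmethod
    def from_sequence(
        cls,
        sequence: str,
        start: int = 0,
        scale: str = "monoisotopic",
        table: ResidueMassTable | None = None,
    ) -> "Peptide":
        return cls(
            sequence=sequence,
            start=start,
            end=start + len(sequence),
            mass=peptide_mass(sequence, scale, table),
            cys_positions=tuple(i for i, aa in enumerate(sequence) if aa == "C"),
        )

    @classmethod
    def from_mass(cls, mass: float, n_cys: int = 1, label: str | None = None) -> "Peptide":
        return cls(
            sequence=None,
            start=-1,
            end=-1,
            mass=float(mass),
            cys_positions=tuple(range(n_cys)),
            label=label or f"m{mass:g}",
        )

    @property
    def n_cys(self) -> int:
        return len(self.cys_positions)

    @property
    def name(self) -> str:
        return self.sequence if self.sequence is not None else (self.label or "?")

    def __len__(self) -> int:
        if self.sequence is None:
            raise TypeError("mass-only peptide has no length")
        return len(self.sequence)


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

#: Cleavage rules: C-terminal to the named residues unless followed by proline.
ENZYME_RULES = {
    "trypsin": r"[KR](?!P)",
    "chymotrypsin": r"[FWY](?!P)",
}


def digest(
    protein: str,
    enzyme: str = "trypsin",
    missed_cleavages: int = 0,
    scale: str = "monoisotopic",
    table: ResidueMassTable | None = None,
) -> list[Peptide]:
    """In-silico proteolytic digest with up to ``missed_cleavages`` skips.

    Returns peptides ordered by (start, end).
    """
    if not protein:
        raise ValueError("empty protein sequence")
    if enzyme not in ENZYME_RULES:
        raise ValueError(
            f"unknown enzyme {enzyme!r}; supported: {', '.join(sorted(ENZYME_RULES))}"
        )
    pieces = _ptparser.icleave(
        protein, ENZYME_RULES[enzyme], missed_cleavages=missed_cleavages, regex=True
    )
    peptides = [
        Peptide.from_sequence(seq, start=start, scale=scale, table=table)
        for start, seq in pieces
    ]
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def extract_ccp(peptides: Iterable[Peptide]) -> list[Peptide]:
    """Cysteine-containing peptides, sorted ascending by mass.

    Ties are broken by (start, sequence) so the ordering is total.
    """
    ccp = [p for p in peptides if p.n_cys >= 1]
    ccp.sort(key=lambda p: (p.mass, p.start, p.name))
    return ccp


# ---------------------------------------------------------------------------
# Disulfide-bonded structures
# ---------------------------------------------------------------------------

#: One side of a bond: (peptide index within the structure, cysteine offset).
BondEnd = tuple[int, int]
Bond = tuple[BondEnd, BondEnd]


def structure_mass(peptide_masses: Sequence[float], n_bonds: int) -> float:
    """Neutral mass of a disulfide-bonded structure: sum minus 2H per bond."""
    if not peptide_masses:
        raise ValueError("a structure needs at least one peptide")
    if n_bonds < 1:
        raise ValueError("a disulfide structure must contain at least one bond")
    return sum(peptide_masses) - SS_BOND_DELTA * n_bonds


@dataclass(frozen=True)
class DisulfideStructure:
    """1..k peptides joined by ``n_bonds`` S-S bonds.

    ``bonded_pairs`` is None while the structure is only a mass-space
    element; concrete cysteine assignments are enumerated later via
    :func:`enumerate_bond_assignments`.
    """

    peptides: tuple[Peptide, ...]
    n_bonds: int
    mass: float
    bonded_pairs: tuple[Bond, ...] | None = None

    @property
    def total_cys(self) -> int:
        return sum(p.n_cys for p in self.peptides)

    @property
    def name(self) -> str:
        return " - ".join(p.name for p in self.peptides)

    def extended(self, peptide: Peptide) -> "DisulfideStructure":
        """Attach one more peptide through one additional S-S bond."""
        return DisulfideStructure(
            peptides=self.peptides + (peptide,),
            n_bonds=self.n_bonds + 1,
            mass=self.mass + peptide.mass - SS_BOND_DELTA,
        )


def make_structure(peptides: Sequence[Peptide], n_bonds: int) -> DisulfideStructure:
    peptides = tuple(peptides)
    total_cys = sum(p.n_cys for p in peptides)
    if n_bonds >= 1 and 2 * n_bonds > total_cys:
        raise ValueError(
            f"{n_bonds} bonds need {2 * n_bonds} cysteines, structure has {total_cys}"
        )
    if len(peptides) == 1 and n_bonds >= 1 and peptides[0].n_cys < 2:
        raise ValueError("an intra-bonded peptide needs at least two cysteines")
    if n_bonds >= 1:
        mass = structure_mass([p.mass for p in peptides], n_bonds)
    else:
        if len(peptides) != 1:
            raise ValueError("a bond-free structure is a single peptide")
        mass = peptides[0].mass
    return DisulfideStructure(peptides=peptides, n_bonds=n_bonds, mass=mass)


def enumerate_bond_assignments(
    structure: DisulfideStructure, limit: int = 200
) -> list[DisulfideStructure]:
    """All concrete cysteine pairings realizing the structure's bond count.

    Each assignment uses every cysteine at most once and connects all
    peptides of the structure into a single molecule.  The enumeration is
    capped at ``limit`` assignments (candidate lists are small in
    practice; the cap guards pathological cysteine-rich inputs).
    """
    if structure.bonded_pairs is not None:
        return [structure]
    if structure.n_bonds == 0:
        return []
    slots: list[BondEnd] = [
        (i, off) for i, p in enumerate(structure.peptides) for off in p.cys_positions
    ]
    k = len(structure.peptides)
    out: list[DisulfideStructure] = []
    for bonds in combinations(combinations(slots, 2), structure.n_bonds):
        used: set[BondEnd] = set()
        ok = True
        for (a, b) in bonds:
            if a in used or b in used:
                ok = False
                break
            used.add(a)
            used.add(b)
        if not ok:
            continue
        if k > 1 and not _connects_all(bonds, k):
            continue
        out.append(replace(structure, bonded_pairs=tuple(bonds)))
        if len(out) >= limit:
            break
    return out


def _connects_all(bonds: Sequence[Bond], k: int) -> bool:
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (i, _), (j, _) in bonds:
        parent[find(i)] = find(j)
    return len({find(i) for i in range(k)}) == 1


# ---------------------------------------------------------------------------
# Connectivity-pattern counting
# ---------------------------------------------------------------------------


def count_patterns(n_bonded_cysteines: int) -> int:
    """Number of distinct perfect pairings of ``n`` bonded cysteines.

    n! / ((n/2)! * 2^(n/2)), i.e. the double factorial (n-1)!! -- the size
    of the full connectivity search space for n cysteines all engaged in
    disulfide bonds.
    """
    n = n_bonded_cysteines
    if n < 0 or n % 2:
        raise ValueError("the number of bonded cysteines must be even and >= 0")
    if n == 0:
        return 1
    half = n // 2
    return math.factorial(n) // (math.factorial(half) * 2**half)
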