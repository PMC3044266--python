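"""Second-stage search: fragment mass space (FMS) and Validation Matching.

Generates multi-ion theoretical fragments (a, b, b-water, b-ammonia, c,
x, y, y-water, y-ammonia, z) for the peptides of an Initial Match,
combines them into disulfide-bonded fragment structures, trims the
resulting mass list with the same (1+delta) scheme used for precursors,
and matches it against MS/MS peaks.

Which fragments keep the S-S bridge follows from the cleavage position:
a backbone fragment that spans a bonded cysteine remains covalently
attached to the partner peptide (intact or itself fragmented), while a
fragment on the far side of the cysteine is released free.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .masschem import (
    CO,
    NH3,
    PROTON,
    SS_BOND_DELTA,
    WATER,
    DisulfideStructure,
    Peptide,
    ResidueMassTable,
    default_table,
)
from .dms import InitialMatch, MassEntry, MassList, trim

logger = logging.getLogger("sslinker.fms")

#: The ten supported backbone ion types.  "bo"/"yo" are the water-loss
#: ions (b°, y°), "bstar"/"ystar" the ammonia-loss ions (b*, y*).
ION_TYPES = ("a", "b", "bo", "bstar", "c", "x", "y", "yo", "ystar", "z")

_NTERM = {"a", "b", "bo", "bstar", "c"}
_CTERM = {"x", "y", "yo", "ystar", "z"}

#: Neutral-mass offsets from the b / y backbone sums.  z uses the
#: radical z-dot convention (y - NH3 + H); classical z is y - NH3.
_NTERM_OFFSET = {"a": -CO, "b": 0.0, "bo": -WATER, "bstar": -NH3, "c": +NH3}
_CTERM_OFFSET = {"x": CO - 2 * 1.0078250319, "y": 0.0, "yo": -WATER, "ystar": -NH3}

Z_DOT = "zdot"
Z_CLASSICAL = "classical"


def _z_offset(convention: str) -> float:
    if convention == Z_DOT:
        return -NH3 + 1.0078250319
    if convention == Z_CLASSICAL:
        return -NH3
    raise ValueError(f"unknown z-ion convention {convention!r}")


@dataclass(frozen=True)
class FragmentIon:
    """An ion-type-resolved sub-fragment of one peptide.

    ``span`` is the half-open residue range retained (offsets within the
    peptide); ``ion_type`` is one of :data:`ION_TYPES` or ``"intact"``
    for the whole, uncleaved peptide.
    """

    peptide: Peptide
    ion_type: str
    cleavage_index: int
    span: tuple[int, int]
    neutral_mass: float

    def covers(self, offset: int) -> bool:
        return self.span[0] <= offset < self.span[1]

    @property
    def name(self) -> str:
        if self.ion_type == "intact":
            return f"[{self.peptide.name}]"
        return f"{self.ion_type}{self.cleavage_index}({self.peptide.name})"


def gen_frags(
    peptides: Sequence[Peptide],
    ion_types: Iterable[str] = ION_TYPES,
    table: ResidueMassTable | None = None,
    z_convention: str = Z_DOT,
) -> list[FragmentIon]:
    """All backbone fragments of the requested ion types, plus intact forms.

    For a peptide of n residues every cleavage index 1..n-1 is emitted
    per requested type; neutral masses derive from the b/y backbone sums
    (b = sum of N-terminal residues, y = sum of C-terminal residues plus
    water) shifted by the per-type offsets.
    """
    ion_types = tuple(ion_types)
    if not peptides:
        raise ValueError("no peptides given")
    if not ion_types:
        raise ValueError("no ion types requested")
    unknown = set(ion_types) - set(ION_TYPES)
    if unknown:
        raise ValueError(f"unsupported ion types: {sorted(unknown)}")
    table = table or default_table()
    out: list[FragmentIon] = []
    for pep in peptides:
        if pep.sequence is None:
            raise ValueError(f"peptide {pep.name} has no sequence; cannot fragment")
        n = len(pep.sequence)
        residue = [table.residue_mass(aa) for aa in pep.sequence]
        prefix = np.concatenate([[0.0], np.cumsum(residue)])
        out.append(
            FragmentIon(pep, "intact", n, (0, n), pep.mass)
        )
        for idx in range(1, n):
            b = prefix[idx]
            y = prefix[n] - prefix[n - idx] + WATER
            for t in ion_types:
                if t in _NTERM:
                    out.append(FragmentIon(pep, t, idx, (0, idx), b + _NTERM_OFFSET[t]))
                elif t == "z":
                    out.append(FragmentIon(pep, t, idx, (n - idx, n), y + _z_offset(z_convention)))
                else:
                    out.append(FragmentIon(pep, t, idx, (n - idx, n), y + _CTERM_OFFSET[t]))
    return out


@dataclass(frozen=True)
class FragmentStructure:
    """1..k fragments/intact peptides joined by the Initial Match's bonds."""

    components: tuple[FragmentIon, ...]
    n_bonds: int
    neutral_mass: float

    @property
    def name(self) -> str:
        return " + ".join(f.name for f in self.components)


def enumerate_fragment_structures(
    structure: DisulfideStructure,
    ion_types: Iterable[str] = ION_TYPES,
    table: ResidueMassTable | None = None,
    z_convention: str = Z_DOT,
) -> list[FragmentStructure]:
    """All disulfide-bonded fragment structures of a concretely bonded IM.

    For each non-empty subset of the structure's peptides and one
    fragment (or intact form) per member, the assigned S-S bonds whose
    two cysteines are both covered are kept; the combination is valid
    when no bond dangles (one side covered, the other absent) and the
    kept bonds connect the chosen peptides into a single molecule.  For a
    single intra-bonded peptide the two-piece case (an N-terminal and a
    C-terminal fragment, each covering one bonded cysteine) is also
    enumerated.
    """
    if structure.bonded_pairs is None:
        raise ValueError("fragment enumeration needs concrete bond assignments")
    frags_by_pep = {
        i: gen_frags([p], ion_types, table, z_convention)
        for i, p in enumerate(structure.peptides)
    }
    bonds = structure.bonded_pairs
    k = len(structure.peptides)
    out: list[FragmentStructure] = []
    for mask in range(1, 1 << k):
        members = [i for i in range(k) if mask >> i & 1]
        inside = [b for b in bonds if b[0][0] in members and b[1][0] in members]
        crossing = [
            b
            for b in bonds
            if (b[0][0] in members) != (b[1][0] in members)
        ]
        for combo in product(*(frags_by_pep[i] for i in members)):
            chosen = dict(zip(members, combo))
            # a bond to an absent peptide must not be covered on our side
            if any(
                chosen[e[0]].covers(e[1])
                for b in crossing
                for e in b
                if e[0] in members
            ):
                continue
            kept = []
            dangling = False
            for b in inside:
                c0 = chosen[b[0][0]].covers(b[0][1])
                c1 = chosen[b[1][0]].covers(b[1][1])
                if c0 and c1:
                    kept.append(b)
                elif c0 or c1:
                    dangling = True
                    break
            if dangling:
                continue
            if len(members) > 1 and not _kept_connect(kept, members):
                continue
            mass = sum(f.neutral_mass for f in combo) - SS_BOND_DELTA * len(kept)
            out.append(FragmentStructure(tuple(combo), len(kept), mass))
    out.extend(_intra_two_piece(structure, frags_by_pep, bonds))
    return out


def _kept_connect(kept: Sequence, members: Sequence[int]) -> bool:
    parent = {i: i for i in members}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (i, _), (j, _) in kept:
        parent[find(i)] = find(j)
    return len({find(i) for i in members}) == 1


def _intra_two_piece(structure, frags_by_pep, bonds) -> list[FragmentStructure]:
    """Double-cleavage products of a single intra-bonded peptide."""
    out: list[FragmentStructure] = []
    if len(structure.peptides) != 1:
        return out
    for (i, c1), (j, c2) in bonds:
        nterm = [f for f in frags_by_pep[0] if f.ion_type in _NTERM]
        cterm = [f for f in frags_by_pep[0] if f.ion_type in _CTERM or f.ion_type == "z"]
        lo, hi = min(c1, c2), max(c1, c2)
        for fa in nterm:
            if not (fa.covers(lo) and not fa.covers(hi)):
                continue
            for fb in cterm:
                if not (fb.covers(hi) and not fb.covers(lo)):
                    continue
                if fa.span[1] > fb.span[0]:
                    continue  # overlapping cleavages cannot coexist
                mass = fa.neutral_mass + fb.neutral_mass - SS_BOND_DELTA
                out.append(FragmentStructure((fa, fb), 1, mass))
    return out


# ---------------------------------------------------------------------------
# Approximate FMS and validation matching
# ---------------------------------------------------------------------------


@dataclass
class FmsIndex:
    """The FMS of one Initial Match, built once and reused per peak.

    Trimming always retains the largest mass below the current
    exclusion cutoff (the Validation-Match candidate), so for any
    product-ion value the declared candidate is the largest exact FMS
    mass below ``target + t_vm`` -- a bisection on the raw entries.
    The trimmed ``retained`` list is kept for search-space accounting.
    """

    entries: list[MassEntry]
    retained: list[MassEntry]
    trimmed: list[MassEntry]
    delta_trim: float = 1e-9

    def __post_init__(self):
        self._masses = [m for m, _ in self.entries]

    @property
    def size(self) -> int:
        return len(self.retained)

    def masslist(self, cutoff: float) -> MassList:
        from .dms import trim as _trim

        return _trim([e for e in self.entries if e[0] <= cutoff], self.delta_trim)

    def declare(self, target: float, t_vm: float) -> float | None:
        """Largest candidate mass <= target + t_vm, if within t_vm of target."""
        hi = bisect_right(self._masses, target + t_vm)
        if hi == 0:
            return None
        m = self._masses[hi - 1]
        return m if abs(m - target) <= t_vm else None

    def window(self, target: float, t_vm: float) -> list[FragmentStructure]:
        lo = bisect_left(self._masses, target - t_vm)
        hi = bisect_right(self._masses, target + t_vm)
        out: list[FragmentStructure] = []
        for _, structs in self.entries[lo:hi]:
            out.extend(structs)
        return out


def build_fms(
    structure: DisulfideStructure,
    delta_trim: float,
    ion_types: Iterable[str] = ION_TYPES,
    table: ResidueMassTable | None = None,
    z_convention: str = Z_DOT,
) -> FmsIndex:
    """Enumerate, sort, collapse and trim the FMS of one bonded structure."""
    structs = enumerate_fragment_structures(structure, ion_types, table, z_convention)
    structs.sort(key=lambda s: s.neutral_mass)
    entries: list[MassEntry] = []
    for s in structs:
        if entries and abs(s.neutral_mass - entries[-1][0]) <= 1e-6:
            entries[-1] = (entries[-1][0], entries[-1][1] + (s,))
        else:
            entries.append((s.neutral_mass, (s,)))
    trimmed = trim(entries, delta_trim)
    return FmsIndex(
        entries=entries,
        retained=trimmed.entries,
        trimmed=trimmed.trimmed,
        delta_trim=delta_trim,
    )


def approx_fms(
    initial_match: InitialMatch | DisulfideStructure,
    tms_value: float,
    delta_trim: float,
    t_vm: float,
    ion_types: Iterable[str] = ION_TYPES,
    table: ResidueMassTable | None = None,
) -> tuple[MassList, "ValidationMatch | None"]:
    """Approximate FMS for one product-ion mass value.

    Masses above ``tms_value + t_vm`` are discarded; a Validation Match
    is declared iff the largest retained mass lies within ``t_vm`` of
    ``tms_value``.
    """
    if delta_trim <= 0:
        raise ValueError("delta_trim must be positive")
    if t_vm <= 0:
        raise ValueError("t_vm must be positive")
    structure = (
        initial_match.structure
        if isinstance(initial_match, InitialMatch)
        else initial_match
    )
    index = build_fms(structure, delta_trim, ion_types, table)
    masslist = index.masslist(tms_value + t_vm)
    declared = index.declare(tms_value, t_vm)
    if declared is None:
        return masslist, None
    structs = tuple(index.window(tms_value, t_vm))
    vm = ValidationMatch(
        structures=structs,
        peak=(tms_value + PROTON, 1.0),
        charge=0,
        neutral_mass=tms_value,
        delta=min(abs(s.neutral_mass - tms_value) for s in structs),
    )
    return masslist, vm


@dataclass(frozen=True)
class ValidationMatch:
    """An FMS mass within T_VM of a (neutralized) product-ion peak.

    ``structures`` lists every fragment structure whose exact mass falls
    inside the match window; each contributes one match to the
    intensity-weighted score.
    """

    structures: tuple[FragmentStructure, ...]
    peak: tuple[float, float]
    charge: int
    neutral_mass: float
    delta: float

    @property
    def fragment_structure(self) -> FragmentStructure:
        return self.structures[0]

    @property
    def n_matches(self) -> int:
        return len(self.structures)


def find_validation_matches(
    initial_match: InitialMatch | DisulfideStructure,
    spectrum: Sequence[tuple[float, float]],
    delta_trim: float,
    t_vm: float,
    ion_types: Iterable[str] = ION_TYPES,
    intensity_floor: float = 0.10,
    charges: Sequence[int] = (1,),
    table: ResidueMassTable | None = None,
    fms: FmsIndex | None = None,
) -> list[ValidationMatch]:
    """Match every sufficiently intense peak against the FMS of one IM.

    Peaks below ``intensity_floor`` times the base-peak intensity are
    ignored.  Peaks are read as singly-protonated m/z by default; each
    charge in ``charges`` is neutralized as m/z*z - z*proton and tested.
    The FMS is built once per Initial Match and reused across peaks.
    """
    if not spectrum:
        raise ValueError("empty spectrum")
    structure = (
        initial_match.structure
        if isinstance(initial_match, InitialMatch)
        else initial_match
    )
    if fms is None:
        fms = build_fms(structure, delta_trim, ion_types, table)
    max_intensity = max(i for _, i in spectrum)
    out: list[ValidationMatch] = []
    for mz, intensity in spectrum:
        if intensity < intensity_floor * max_intensity:
            continue
        for z in charges:
            neutral = mz * z - z * PROTON
            declared = fms.declare(neutral, t_vm)
            if declared is None:
                continue
            structs = tuple(fms.window(neutral, t_vm))
            if not structs:
                continue
            out.append(
                ValidationMatch(
                    structures=structs,
                    peak=(mz, intensity),
                    charge=z,
                    neutral_mass=neutral,
                    delta=min(abs(s.neutral_mass - neutral) for s in structs),
                )
            )
            break  # first matching charge state wins
    return out
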