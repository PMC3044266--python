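"""First-stage search: approximate disulfide precursor mass space (DMS).

Implements the (1+eps)-approximation of the subset-sum-style construction
of all disulfide-bonded peptide structure masses, and Initial-Match
detection against precursor (PMS) values.

The construction iterates cysteine-containing peptides (CCPs) in
ascending mass order.  At each step a temporary set holds the peptide
alone (and, when it carries two or more cysteines, its intra-bonded
form) together with every retained structure extended by the peptide
through one additional S-S bond.  Candidates heavier than the precursor
mass plus the match window are discarded, the temporary set is merged
into the running list with duplicates collapsed, and the list is trimmed:
scanning upward, an element is kept only if it exceeds the last kept
element by more than the factor (1+eps).  Every removed mass m therefore
leaves a retained representative m* with m/(1+eps) <= m* <= m, which is
the soundness guarantee of the scheme.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Sequence

from .masschem import (
    DisulfideStructure,
    Peptide,
    enumerate_bond_assignments,
    make_structure,
)

logger = logging.getLogger("sslinker.dms")

#: Two masses closer than this are considered the same DMS element.
DEDUP_TOL = 1e-6

#: A mass value plus every structure realizing it.
MassEntry = tuple[float, tuple[DisulfideStructure, ...]]


@dataclass
class MassList:
    """Retained mass entries plus the trimmed set, provenance preserved."""

    entries: list[MassEntry] = field(default_factory=list)
    trimmed: list[MassEntry] = field(default_factory=list)

    @property
    def masses(self) -> list[float]:
        return [m for m, _ in self.entries]

    def all_entries(self) -> list[MassEntry]:
        """Retained and trimmed entries together, sorted by mass."""
        return sorted(self.entries + self.trimmed, key=lambda e: e[0])


@dataclass(frozen=True)
class InitialMatch:
    """A DMS mass within T_IM of a precursor mass value."""

    structure: DisulfideStructure
    pms_value: float
    delta: float

    @property
    def mass(self) -> float:
        return self.structure.mass


def _check_sorted(masses: Sequence[float]) -> None:
    for a, b in zip(masses, masses[1:]):
        if b < a:
            raise ValueError("input mass list must be sorted ascending")


def trim(entries: Sequence[MassEntry], epsilon: float) -> MassList:
    """Keep-first (1+eps) trimming of an ascending mass list.

    The first element is retained; each subsequent mass y is retained
    iff y > last_retained * (1 + eps).  The largest element of the list
    is additionally always retained: after the exclusion cutoff it is
    the Initial-Match candidate the search inspects, so thinning must
    never remove it (the published worked example keeps its top value
    2050 while trimming 2022 against it).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    _check_sorted([m for m, _ in entries])
    out = MassList()
    last = None
    for entry in entries:
        if last is None or entry[0] > last * (1.0 + epsilon):
            out.entries.append(entry)
            last = entry[0]
        else:
            out.trimmed.append(entry)
    if out.trimmed and out.trimmed[-1][0] > out.entries[-1][0]:
        out.entries.append(out.trimmed.pop())
    return out


def merge(a: Sequence[MassEntry], b: Sequence[MassEntry]) -> list[MassEntry]:
    """Sorted union of two sorted entry lists.

    Masses equal within ``DEDUP_TOL`` collapse into one entry whose
    provenance lists are concatenated.
    """
    _check_sorted([m for m, _ in a])
    _check_sorted([m for m, _ in b])
    out: list[MassEntry] = []
    i = j = 0
    while i < len(a) or j < len(b):
        if j >= len(b) or (i < len(a) and a[i][0] <= b[j][0]):
            nxt = a[i]
            i += 1
        else:
            nxt = b[j]
            j += 1
        if out and abs(nxt[0] - out[-1][0]) <= DEDUP_TOL:
            out[-1] = (out[-1][0], out[-1][1] + nxt[1])
        else:
            out.append(nxt)
    return out


def approx_dms(
    ccp: Sequence[Peptide],
    pms_value: float,
    epsilon: float,
    t_im: float,
    k_max: int = 3,
    scale_epsilon: bool = False,
) -> tuple[MassList, InitialMatch | None]:
    """Approximate DMS construction for one precursor mass value.

    Returns the final retained/trimmed mass list and, when the largest
    retained mass lies within ``t_im`` of ``pms_value`` and carries at
    least one bonded structure, the Initial Match at that mass.

    Per-step trimming with the full ``epsilon`` compounds over the
    iterations, so the retained optimum is only guaranteed within
    (1+epsilon)^k of the exhaustive one; with ``scale_epsilon`` each of
    the k trim rounds uses epsilon/(2k), which restores the strict
    (1+epsilon) guarantee at the price of a longer list.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if t_im <= 0:
        raise ValueError("t_im must be positive")
    _check_sorted([p.mass for p in ccp])
    if scale_epsilon and ccp:
        epsilon = epsilon / (2.0 * len(ccp))
    cutoff = pms_value + t_im
    dms = MassList()
    for pep in ccp:
        temp: list[MassEntry] = []

        def _add(struct: DisulfideStructure) -> None:
            if struct.mass <= cutoff:
                temp.append((struct.mass, (struct,)))

        _add(make_structure([pep], 0))
        if pep.n_cys >= 2:
            _add(make_structure([pep], 1))
        for _, structs in dms.entries:
            for s in structs:
                if len(s.peptides) >= k_max:
                    continue
                # extension is pure mass arithmetic: retained elements must
                # stand in for trimmed ones under any future extension, so
                # cysteine feasibility is checked only when candidates are
                # expanded into concrete bond assignments
                _add(s.extended(pep))
        if not temp:
            continue
        temp.sort(key=lambda e: e[0])
        # collapse duplicates inside the batch before merging
        temp = merge(temp, [])
        merged = merge(dms.entries, temp)
        trimmed_now = trim(merged, epsilon)
        dms.entries = trimmed_now.entries
        dms.trimmed.extend(trimmed_now.trimmed)
    match = _declare_match(dms, pms_value, t_im)
    return dms, match


def _declare_match(dms: MassList, pms_value: float, t_im: float) -> InitialMatch | None:
    """Paper rule: an IM exists iff the largest retained mass is within T_IM.

    Bond-free singleton masses populate the DMS but cannot themselves be
    an Initial Match, so the scan walks down while still inside the match
    window until a bonded structure is found.
    """
    for m, structs in reversed(dms.entries):
        if abs(m - pms_value) > t_im:
            return None
        bonded = tuple(
            s for s in structs if s.n_bonds >= 1 and s.total_cys >= 2 * s.n_bonds
        )
        if bonded:
            best = min(bonded, key=lambda s: abs(s.mass - pms_value))
            return InitialMatch(structure=best, pms_value=pms_value, delta=abs(m - pms_value))
    return None


def window_candidates(
    dms: MassList, pms_value: float, t_im: float
) -> list[DisulfideStructure]:
    """All bonded structures (retained or trimmed) within T_IM of the precursor.

    Trimming is a computational device: a removed mass always has a
    retained representative within factor (1+eps), so once a match is
    declared at the representative the physically meaningful candidates
    are every structure whose exact mass falls inside the match window.
    """
    entries = dms.all_entries()
    masses = [m for m, _ in entries]
    lo = bisect_left(masses, pms_value - t_im)
    hi = bisect_right(masses, pms_value + t_im)
    out: list[DisulfideStructure] = []
    for m, structs in entries[lo:hi]:
        out.extend(
            s for s in structs if s.n_bonds >= 1 and s.total_cys >= 2 * s.n_bonds
        )
    return out


def find_initial_matches(
    ccp: Sequence[Peptide],
    pms: Sequence[float],
    epsilon: float,
    t_im: float,
    k_max: int = 3,
) -> list[InitialMatch]:
    """One approximate DMS run per precursor value.

    For every declared match the candidate structures in the full match
    window are expanded into concrete cysteine-pair assignments (needed
    downstream to decide which fragments carry the S-S bridge); one
    InitialMatch is emitted per assigned structure.
    """
    matches: list[InitialMatch] = []
    for pms_value in pms:
        dms, declared = approx_dms(ccp, pms_value, epsilon, t_im, k_max)
        logger.debug(
            "PMS %.3f: DMS retained=%d trimmed=%d match=%s",
            pms_value, len(dms.entries), len(dms.trimmed), declared is not None,
        )
        if declared is None:
            continue
        for cand in window_candidates(dms, pms_value, t_im):
            delta = abs(cand.mass - pms_value)
            for assigned in enumerate_bond_assignments(cand):
                matches.append(
                    InitialMatch(structure=assigned, pms_value=pms_value, delta=delta)
                )
    return matches
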