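"""Bond-level scoring and globally consistent disulfide topology.

Each putative bond (a cysteine pair supported by an Initial Match and
its Validation Matches) receives an intensity-weighted match score

    V_s = 100 * sum_i VM_i * I_N(i) / sum_i TMS_i * I_N(i)

where I_N is the base-peak-normalized intensity.  The numerator counts
every (fragment structure, peak) validation pair -- a peak matched by
several theoretical fragment structures contributes once per match, so
V_s can exceed 100.  The denominator sums the normalized intensities of
the experimental peaks above the intensity floor.

Confidence scores pp and pp2 ask whether the number of matched peaks,
respectively the total matched abundance, could be random: pp is the
-log10 binomial tail probability of the match count, pp2 the -log10
Monte-Carlo probability that a random same-size peak subset reaches the
observed matched intensity.

Scored bonds above a threshold become weighted edges of a graph on the
protein's cysteines; the reported topology is the maximum-weight
matching of that graph (a blossom-class algorithm), which enforces that
no cysteine participates in more than one bond.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .fms import ValidationMatch

logger = logging.getLogger("sslinker.score")

#: Cysteine pair as 1-based residue positions in the parent protein.
CysPair = tuple[int, int]

SCORE_CLIP = 300.0


def normalize_intensity(
    spectrum: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Scale peak intensities to (0, 1] by the base-peak intensity."""
    if not spectrum:
        raise ValueError("empty spectrum")
    top = max(i for _, i in spectrum)
    if top <= 0:
        raise ValueError("maximum peak intensity must be positive")
    return [(mz, i / top) for mz, i in spectrum]


def match_score(
    vms: Sequence[ValidationMatch],
    spectrum: Sequence[tuple[float, float]],
    intensity_floor: float = 0.10,
    floor_restricted: bool = True,
) -> float:
    """Intensity-weighted validation score V_s for one putative bond.

    ``spectrum`` must be normalized.  With ``floor_restricted`` the
    denominator sums only peaks at or above the intensity floor (the
    same population offered for matching); set it False to sum all
    peaks.
    """
    if floor_restricted:
        denom = sum(i for _, i in spectrum if i >= intensity_floor)
    else:
        denom = sum(i for _, i in spectrum)
    if denom <= 0:
        raise ValueError("zero denominator: no peaks above the intensity floor")
    numer = sum(vm.n_matches * vm.peak[1] for vm in vms)
    return 100.0 * numer / denom


def pp_scores(
    vms: Sequence[ValidationMatch],
    spectrum: Sequence[tuple[float, float]],
    fms_size: int,
    t_vm: float,
    mass_range: float,
    intensity_floor: float = 0.10,
    n_draws: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Random-match confidence scores (pp, pp2), both in [0, 300].

    pp: with q = min(1, 2*t_vm*fms_size/mass_range) the per-peak chance
    of hitting any retained FMS window, pp = -log10 P(X >= n_matched)
    for X ~ Binomial(n_peaks, q).  pp2: fraction of ``n_draws`` random
    same-size peak subsets whose normalized-intensity total reaches the
    observed matched total, -log10-transformed.
    """
    if mass_range <= 0:
        raise ValueError("mass_range must be positive")
    peaks = [(mz, i) for mz, i in spectrum if i >= intensity_floor * max(i for _, i in spectrum)]
    matched = {vm.peak for vm in vms}
    n_vm = len(matched)
    if n_vm == 0:
        return 0.0, 0.0
    n_peaks = max(len(peaks), n_vm)
    q = min(1.0, 2.0 * t_vm * fms_size / mass_range)
    tail = float(stats.binom.sf(n_vm - 1, n_peaks, q))
    pp = 0.0 if tail >= 1.0 else min(SCORE_CLIP, -math.log10(max(tail, 1e-300)))
    intensities = np.array([i for _, i in peaks])
    observed = sum(i for _, i in matched)
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(n_draws, int(2e6 // max(len(intensities), 1))))
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        u = rng.random((m, len(intensities)))
        idx = np.argpartition(u, n_vm - 1, axis=1)[:, :n_vm]
        sums = intensities[idx].sum(axis=1)
        hits += int((sums >= observed - 1e-12).sum())
        done += m
    frac = hits / n_draws
    pp2 = SCORE_CLIP if frac == 0 else min(SCORE_CLIP, -math.log10(frac))
    return pp, max(0.0, pp2)


@dataclass(frozen=True)
class BondScore:
    """Evidence for one putative S-S bond between two cysteines."""

    cys_pair: CysPair
    v_s: float
    pp: float
    pp2: float
    vms: tuple[ValidationMatch, ...] = ()
    precursor: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "cys_pair", _canon(self.cys_pair))


def _canon(pair: CysPair) -> CysPair:
    a, b = pair
    return (a, b) if a <= b else (b, a)


def build_bond_graph(
    scored_bonds: Iterable[BondScore], threshold: float
) -> nx.Graph:
    """Graph on cysteines with one edge per pair scoring at or above threshold.

    When several Initial Matches support the same cysteine pair only the
    best-scoring evidence is kept.
    """
    graph = nx.Graph()
    for bond in scored_bonds:
        if bond.v_s < threshold:
            continue
        u, v = bond.cys_pair
        if u == v:
            continue
        if graph.has_edge(u, v) and graph[u][v]["bond"].v_s >= bond.v_s:
            continue
        graph.add_edge(u, v, weight=bond.v_s, bond=bond)
    return graph


def max_weight_topology(graph: nx.Graph) -> set[CysPair]:
    """Maximum-weight matching of the bond graph: the reported topology."""
    matching = nx.max_weight_matching(graph)
    return {_canon(edge) for edge in matching}


@dataclass(frozen=True)
class TopologyEvaluation:
    """Confusion counts and the standard connectivity quality measures.

    Undefined ratios (empty positive or negative class) are None.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    q_c: float | None
    q_nc: float | None
    q_2: float | None
    c: float | None


def evaluate(
    predicted: Iterable[CysPair],
    known: Iterable[CysPair],
    all_cys_pairs: Iterable[CysPair],
) -> TopologyEvaluation:
    """Sensitivity Q_c = TP/P, specificity Q_nc = TN/N, accuracy
    Q_2 = (TP+TN)/(P+N) and the Matthews correlation coefficient,
    computed over an explicit universe of candidate cysteine pairs."""
    universe = {_canon(p) for p in all_cys_pairs}
    pos = {_canon(p) for p in known}
    if not pos <= universe:
        raise ValueError("known bonds must be contained in the candidate pairs")
    pred = {_canon(p) for p in predicted} & universe
    neg = universe - pos
    tp = len(pred & pos)
    fp = len(pred & neg)
    fn = len(pos) - tp
    tn = len(neg) - fp
    q_c = tp / len(pos) if pos else None
    q_nc = tn / len(neg) if neg else None
    q_2 = (tp + tn) / len(universe) if universe else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    c = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else None
    return TopologyEvaluation(tp=tp, fp=fp, tn=tn, fn=fn, q_c=q_c, q_nc=q_nc, q_2=q_2, c=c)
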