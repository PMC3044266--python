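import itertools
import math

import networkx as nx
import numpy as np
import pytest

from sslinker import (
    BondScore,
    build_bond_graph,
    evaluate,
    match_score,
    max_weight_topology,
    normalize_intensity,
    pp_scores,
)
from sslinker.fms import FragmentStructure, ValidationMatch


def _vm(peak, n_structures=1):
    structs = tuple(
        FragmentStructure(components=(), n_bonds=0, neutral_mass=0.0)
        for _ in range(n_structures)
    )
    return ValidationMatch(structures=structs, peak=peak, charge=1,
                           neutral_mass=peak[0] - 1.00728, delta=0.0)


class TestNormalize:
    def test_examples(self):
        assert [i for _, i in normalize_intensity([(1, 100), (2, 50), (3, 25)])] \
            == [1.0, 0.5, 0.25]
        assert [i for _, i in normalize_intensity([(1, 7)])] == [1.0]

    def test_order_preserved_and_max_one(self):
        rng = np.random.default_rng(0)
        raw = [(float(i), float(v)) for i, v in enumerate(rng.uniform(1, 50, 30))]
        out = normalize_intensity(raw)
        assert max(i for _, i in out) == 1.0
        assert np.argsort([i for _, i in raw]).tolist() == \
            np.argsort([i for _, i in out]).tolist()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_intensity([])


class TestMatchScore:
    SPECTRUM = [(100.0, 1.0), (200.0, 0.5), (300.0, 0.25)]

    def test_all_peaks_matched_once_scores_100(self):
        vms = [_vm(p) for p in self.SPECTRUM]
        assert match_score(vms, self.SPECTRUM) == pytest.approx(100.0)

    def test_no_matches_scores_zero(self):
        assert match_score([], self.SPECTRUM) == 0.0

    def test_partial_match_arithmetic(self):
        vms = [_vm(self.SPECTRUM[0]), _vm(self.SPECTRUM[2])]
        assert match_score(vms, self.SPECTRUM) == pytest.approx(100 * 1.25 / 1.75)

    def test_multiple_structures_per_peak_can_exceed_100(self):
        """A peak matched by several fragment structures counts once per
        match, so scores above 100 are legitimate."""
        vms = [_vm(p, n_structures=3) for p in self.SPECTRUM]
        assert match_score(vms, self.SPECTRUM) == pytest.approx(300.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            match_score([], self.SPECTRUM, intensity_floor=1.5)


class TestPpScores:
    SPECTRUM = [(float(100 + i), 1.0 - 0.04 * i) for i in range(20)]

    def test_no_matches_gives_zero(self):
        pp, pp2 = pp_scores([], self.SPECTRUM, fms_size=50, t_vm=1.0, mass_range=2000)
        assert pp == 0.0 and pp2 == 0.0

    def test_pp_equals_exact_binomial_tail(self):
        """pp reproduces the -log10 of a directly summed binomial tail."""
        vms = [_vm(p) for p in self.SPECTRUM[:10]]
        q = 0.05
        # q = 2 * t_vm * fms_size / mass_range = 0.05
        pp, _ = pp_scores(vms, self.SPECTRUM, fms_size=50, t_vm=1.0, mass_range=2000)
        tail = sum(
            math.comb(20, k) * q**k * (1 - q) ** (20 - k) for k in range(10, 21)
        )
        assert pp == pytest.approx(-math.log10(tail), rel=1e-9)

    def test_pp_monotone_in_match_count(self):
        pps = []
        for n in (2, 5, 9, 14):
            vms = [_vm(p) for p in self.SPECTRUM[:n]]
            pp, _ = pp_scores(vms, self.SPECTRUM, 50, 1.0, 2000)
            pps.append(pp)
        assert pps == sorted(pps)

    def test_pp2_higher_for_top_intensity_matches(self):
        """Matching the most intense peaks is less likely at random than
        matching an arbitrary same-size subset."""
        top = [_vm(p) for p in self.SPECTRUM[:5]]
        rng = np.random.default_rng(1)
        idx = rng.choice(len(self.SPECTRUM), size=5, replace=False)
        random_set = [_vm(self.SPECTRUM[i]) for i in idx]
        _, pp2_top = pp_scores(top, self.SPECTRUM, 50, 1.0, 2000, seed=7)
        _, pp2_rand = pp_scores(random_set, self.SPECTRUM, 50, 1.0, 2000, seed=7)
        assert pp2_top >= pp2_rand


class TestBondGraph:
    def test_threshold_80_excludes_false_positive(self):
        bonds = [BondScore((1, 2), 100.0, 0, 0), BondScore((3, 4), 53.2, 0, 0)]
        graph = build_bond_graph(bonds, threshold=80)
        assert graph.number_of_edges() == 1

    def test_threshold_30_admits_weak_bond(self):
        graph = build_bond_graph([BondScore((1, 2), 30.8, 0, 0)], threshold=30)
        assert graph.number_of_edges() == 1

    def test_empty(self):
        assert build_bond_graph([], 30).number_of_edges() == 0

    def test_best_evidence_kept_per_pair(self):
        bonds = [BondScore((1, 2), 85.0, 0, 0), BondScore((2, 1), 95.0, 0, 0)]
        graph = build_bond_graph(bonds, threshold=80)
        assert graph[1][2]["weight"] == 95.0


def _brute_force_matching(graph):
    """Best matching weight by enumeration over all edge subsets."""
    edges = list(graph.edges(data="weight"))
    best = 0.0
    for r in range(len(edges) + 1):
        for subset in itertools.combinations(edges, r):
            seen = set()
            ok = True
            for u, v, _ in subset:
                if u in seen or v in seen:
                    ok = False
                    break
                seen.update((u, v))
            if ok:
                best = max(best, sum(w for _, _, w in subset))
    return best


class TestMaxWeightTopology:
    def test_chain_example(self):
        g = nx.Graph()
        g.add_weighted_edges_from([(1, 2, 100), (1, 3, 95), (3, 4, 90)])
        topo = max_weight_topology(g)
        assert topo == {(1, 2), (3, 4)}

    def test_single_edge(self):
        g = nx.Graph()
        g.add_edge(1, 2, weight=5.0)
        assert max_weight_topology(g) == {(1, 2)}

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(2, 9))
            g = nx.Graph()
            for u in range(n):
                for v in range(u + 1, n):
                    if rng.random() < 0.4:
                        g.add_edge(u, v, weight=float(rng.uniform(1, 100)))
            topo = max_weight_topology(g)
            got = sum(g[u][v]["weight"] for u, v in topo)
            assert got == pytest.approx(_brute_force_matching(g))
            flat = [v for e in topo for v in e]
            assert len(flat) == len(set(flat))


class TestEvaluate:
    PAIRS = [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]

    def test_perfect_prediction(self):
        known = [(1, 2), (3, 4)]
        ev = evaluate(known, known, self.PAIRS)
        assert (ev.q_c, ev.q_nc, ev.q_2, ev.c) == (1.0, 1.0, 1.0, 1.0)

    def test_half_sensitivity(self):
        """One of two known bonds found, no false positives."""
        ev = evaluate([(1, 2)], [(1, 2), (3, 4)], self.PAIRS)
        assert ev.q_c == pytest.approx(0.50)
        assert ev.q_nc == 1.0

    def test_no_positives_reported_absent(self):
        ev = evaluate([], [], self.PAIRS)
        assert ev.q_c is None and ev.c is None
        assert ev.q_nc == 1.0

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(4)
        universe = self.PAIRS
        for _ in range(20):
            known = [p for p in universe if rng.random() < 0.4]
            pred = [p for p in universe if rng.random() < 0.4]
            ev = evaluate(pred, known, universe)
            tp = sum(p in known for p in pred)
            fp = sum(p not in known for p in pred)
            fn = sum(p not in pred for p in known)
            tn = len(universe) - tp - fp - fn
            assert (ev.tp, ev.fp, ev.tn, ev.fn) == (tp, fp, tn, fn)

    def test_known_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [(9, 10)], self.PAIRS)
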