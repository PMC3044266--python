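import numpy as np
import pytest

from sslinker import (
    CO,
    ION_TYPES,
    NH3,
    PROTON,
    SS_BOND_DELTA,
    WATER,
    Peptide,
    approx_fms,
    build_fms,
    enumerate_fragment_structures,
    find_validation_matches,
    gen_frags,
    peptide_mass,
)

CD = peptide_mass("CD") - WATER  # b2 backbone sum of CDEIHLY
LY = peptide_mass("LY")  # y2 of CDEIHLY


class TestGenFrags:
    @pytest.mark.parametrize(
        "ion_type,expected",
        [
            ("b", 218.036),
            ("y", 294.158),
            ("bo", 200.025),
            ("bstar", 201.009),
            ("a", 190.041),
            ("c", 235.062),
            ("yo", 276.147),
            ("ystar", 277.131),
            ("x", 320.137),
            ("z", 278.139),  # z-dot: y - NH3 + H
        ],
    )
    def test_cleavage_index_2_masses(self, ion_type, expected):
        pep = Peptide.from_sequence("CDEIHLY")
        frags = gen_frags([pep], [ion_type])
        by_index = {f.cleavage_index: f for f in frags if f.ion_type == ion_type}
        assert by_index[2].neutral_mass == pytest.approx(expected, abs=0.01)

    def test_classical_z_convention(self):
        pep = Peptide.from_sequence("CDEIHLY")
        frags = gen_frags([pep], ["z"], z_convention="classical")
        z2 = next(f for f in frags if f.cleavage_index == 2)
        assert z2.neutral_mass == pytest.approx(LY - NH3, abs=1e-3)

    def test_fragment_count_all_types(self):
        pep = Peptide.from_sequence("CDEIHLY")
        frags = gen_frags([pep], ION_TYPES)
        assert len(frags) == 10 * (len("CDEIHLY") - 1) + 1  # + intact

    def test_single_residue_yields_only_intact(self):
        frags = gen_frags([Peptide.from_sequence("C")], ION_TYPES)
        assert [f.ion_type for f in frags] == ["intact"]

    def test_spans_cover_correct_termini(self):
        pep = Peptide.from_sequence("CDEIHLY")
        frags = gen_frags([pep], ["b", "y"])
        for f in frags:
            if f.ion_type == "b":
                assert f.span == (0, f.cleavage_index)
            elif f.ion_type == "y":
                assert f.span == (7 - f.cleavage_index, 7)

    def test_rejects_unknown_ion_type(self):
        with pytest.raises(ValueError, match="w"):
            gen_frags([Peptide.from_sequence("ACK")], ["w"])


def _brute_force_fms(p1, p2, c1, c2, ion_types):
    """Independent enumeration of all fragment-structure masses for a
    two-peptide structure bonded c1(p1)-c2(p2), from first principles."""

    def frag_masses(seq, keep_offset):
        """(mass, covers) for every fragment of seq plus the intact form."""
        res = [peptide_mass(aa) - WATER for aa in seq]
        out = [(sum(res) + WATER, True)]
        n = len(seq)
        for i in range(1, n):
            b = sum(res[:i])
            y = sum(res[n - i:]) + WATER
            for t in ion_types:
                if t in ("a", "b", "bo", "bstar", "c"):
                    off = {"a": -CO, "b": 0, "bo": -WATER, "bstar": -NH3, "c": NH3}[t]
                    out.append((b + off, keep_offset < i))
                else:
                    off = {
                        "x": CO - 2 * 1.0078250319, "y": 0.0, "yo": -WATER,
                        "ystar": -NH3, "z": -NH3 + 1.0078250319,
                    }[t]
                    out.append((y + off, keep_offset >= n - i))
        return out

    f1 = frag_masses(p1, c1)
    f2 = frag_masses(p2, c2)
    masses = set()
    for m, covers in f1 + f2:
        if not covers:
            masses.add(round(m, 6))
    for m1, covers1 in f1:
        if not covers1:
            continue
        for m2, covers2 in f2:
            if covers2:
                masses.add(round(m1 + m2 - SS_BOND_DELTA, 6))
    return masses


def _pair_structure(s1, s2, c1, c2):
    from sslinker import DisulfideStructure, structure_mass

    p1 = Peptide.from_sequence(s1)
    p2 = Peptide.from_sequence(s2, start=50)
    return DisulfideStructure(
        peptides=(p1, p2),
        n_bonds=1,
        mass=structure_mass([p1.mass, p2.mass], 1),
        bonded_pairs=(((0, c1), (1, c2)),),
    )


class TestFragmentStructures:
    def test_matches_brute_force_enumeration(self):
        """Approximate FMS with vanishing trim equals direct enumeration."""
        cases = [
            ("ACDK", "GCLY", 1, 1),
            ("CDEIHL", "KTCAVV", 0, 2),
            ("MCV", "WCG", 1, 1),
        ]
        for s1, s2, c1, c2 in cases:
            structure = _pair_structure(s1, s2, c1, c2)
            index = build_fms(structure, delta_trim=1e-12)
            got = {round(m, 6) for m, _ in index.retained}
            expected = _brute_force_fms(s1, s2, c1, c2, ION_TYPES)
            assert got == expected

    def test_bridge_fragments_carry_partner(self):
        structure = _pair_structure("ACDK", "GCLY", 1, 1)
        # every 2-component structure joins fragments that both span a cysteine
        for fs in enumerate_fragment_structures(structure):
            if len(fs.components) == 2:
                a, b = fs.components
                assert a.covers(1) and b.covers(1)
                assert fs.n_bonds == 1

    def test_intra_bond_fragments(self):
        """A single intra-bonded peptide yields looped and two-piece forms."""
        from sslinker import DisulfideStructure

        pep = Peptide.from_sequence("ACDCK")
        structure = DisulfideStructure(
            peptides=(pep,), n_bonds=1, mass=pep.mass - SS_BOND_DELTA,
            bonded_pairs=(((0, 1), (0, 3)),),
        )
        structs = enumerate_fragment_structures(structure, ["b", "y"])
        intact = [s for s in structs if len(s.components) == 1
                  and s.components[0].ion_type == "intact"]
        assert intact and intact[0].neutral_mass == pytest.approx(
            pep.mass - SS_BOND_DELTA, abs=1e-6
        )
        # b4 spans both cysteines: bonded, mass shifted by -2H
        b4 = [s for s in structs if len(s.components) == 1
              and s.components[0].ion_type == "b" and s.components[0].cleavage_index == 4]
        assert b4 and b4[0].n_bonds == 1
        # b1 covers neither cysteine: free
        b1 = [s for s in structs if len(s.components) == 1
              and s.components[0].ion_type == "b" and s.components[0].cleavage_index == 1]
        assert b1 and b1[0].n_bonds == 0
        # two-piece: b2 (covers C2) + y1..? fragments covering only C4
        two_piece = [s for s in structs if len(s.components) == 2]
        assert any(s.n_bonds == 1 for s in two_piece)


class TestApproxFms:
    def test_self_consistency(self, bonded_pair):
        """Any theoretical structure mass fed back as the product-ion value
        validates with zero mass error."""
        index = build_fms(bonded_pair, delta_trim=1e-9)
        rng = np.random.default_rng(1)
        for m in rng.choice([m for m, _ in index.entries], size=5, replace=False):
            masslist, vm = approx_fms(bonded_pair, float(m), 1e-9, 0.5)
            assert vm is not None
            assert vm.delta == pytest.approx(0.0, abs=1e-9)

    def test_no_match_far_from_structures(self, bonded_pair):
        _, vm = approx_fms(bonded_pair, 10.0, 1e-9, 0.5)
        assert vm is None


class TestFindValidationMatches:
    def test_round_trip_five_peaks(self, bonded_pair):
        index = build_fms(bonded_pair, delta_trim=1e-9)
        rng = np.random.default_rng(2)
        chosen = rng.choice([m for m, _ in index.entries], size=5, replace=False)
        spectrum = [(float(m) + PROTON, 1.0) for m in sorted(chosen)]
        vms = find_validation_matches(bonded_pair, spectrum, 1e-9, 0.5)
        assert len(vms) == 5
        for vm in vms:
            assert vm.delta <= 0.5

    def test_peaks_below_intensity_floor_ignored(self, bonded_pair):
        index = build_fms(bonded_pair, delta_trim=1e-9)
        m = index.entries[0][0]
        spectrum = [(m + PROTON, 0.01), (5000.0, 1.0)]
        vms = find_validation_matches(bonded_pair, spectrum, 1e-9, 0.5,
                                      intensity_floor=0.10)
        assert vms == []

    def test_decoy_only_spectrum_matches_nothing(self, bonded_pair):
        """Peaks placed away from every theoretical mass never validate."""
        index = build_fms(bonded_pair, delta_trim=1e-9)
        theoretical = np.array([m for m, _ in index.entries])
        rng = np.random.default_rng(3)
        decoys = []
        while len(decoys) < 20:
            m = rng.uniform(100, 2100)
            if np.abs(theoretical - m).min() > 0.5:
                decoys.append((m + PROTON, rng.uniform(0.2, 1.0)))
        assert find_validation_matches(bonded_pair, decoys, 1e-9, 0.5) == []

    def test_by_only_never_more_matches_than_all_ions(self, bonded_pair):
        rng = np.random.default_rng(4)
        index = build_fms(bonded_pair, delta_trim=1e-9)
        chosen = rng.choice([m for m, _ in index.entries], size=30, replace=False)
        spectrum = [(float(m) + PROTON, float(rng.uniform(0.2, 1.0)))
                    for m in sorted(chosen)]
        vms_by = find_validation_matches(bonded_pair, spectrum, 1e-9, 1.0, ["b", "y"])
        vms_all = find_validation_matches(bonded_pair, spectrum, 1e-9, 1.0, ION_TYPES)
        n_by = sum(vm.n_matches for vm in vms_by)
        n_all = sum(vm.n_matches for vm in vms_all)
        assert len(vms_by) <= len(vms_all)
        assert n_by <= n_all

    def test_empty_spectrum_rejected(self, bonded_pair):
        with pytest.raises(ValueError):
            find_validation_matches(bonded_pair, [], 1e-9, 0.5)
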