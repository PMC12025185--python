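import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modlys import lysine_triage as triage
from modlys import structure_io as sio
from modlys import surface_analysis as surf
from modlys import synthetic_data as synth
from tests.conftest import pdb_atom_line, ring_of_lysines


def brute_force_bridges(structure, cutoff=4.0):
    """O(N²) all-pairs oracle over charged side-chain atoms."""
    found = {}
    for bkey, batoms in structure.residues.items():
        wanted_b = triage.BASIC_SIDECHAIN_ATOMS.get(bkey[2])
        if not wanted_b:
            continue
        for akey, aatoms in structure.residues.items():
            wanted_a = triage.ACIDIC_SIDECHAIN_ATOMS.get(akey[2])
            if not wanted_a:
                continue
            dmin = math.inf
            for b in batoms:
                if b.name not in wanted_b:
                    continue
                for a in aatoms:
                    if a.name not in wanted_a:
                        continue
                    d = math.dist(b.position, a.position)
                    dmin = min(dmin, d)
            if dmin <= cutoff:
                found[(bkey, akey)] = dmin
    return found


class TestLysReactivity:
    def test_ph_equals_pka_is_semi(self):
        score = triage.lys_reactivity(9.0, 9.0)
        assert score.lys_re == 1.0
        assert score.reactivity_class == "semi"

    def test_reduced_pka_is_high(self):
        score = triage.lys_reactivity(8.92, 9.0)
        assert score.lys_re == pytest.approx(10 ** 0.08)
        assert score.lys_re == pytest.approx(1.2023, abs=1e-4)
        assert score.reactivity_class == "high"

    def test_typical_pka_is_low(self):
        score = triage.lys_reactivity(10.05, 9.0)
        assert score.lys_re == pytest.approx(10 ** -1.05)
        assert score.lys_re == pytest.approx(0.0891, abs=1e-4)
        assert score.reactivity_class == "low"

    def test_boundary_values_are_semi(self):
        assert triage.lys_reactivity(10.0, 9.0).reactivity_class == "semi"  # 0.1
        assert triage.lys_reactivity(9.0, 9.0).reactivity_class == "semi"   # 1.0
        assert triage.lys_reactivity(10.001, 9.0).reactivity_class == "low"
        assert triage.lys_reactivity(8.999, 9.0).reactivity_class == "high"

    @given(
        pka=st.floats(5.0, 14.0),
        ph=st.floats(3.0, 12.0),
    )
    def test_tenfold_per_ph_unit(self, pka, ph):
        base = triage.lys_reactivity(pka, ph).lys_re
        up = triage.lys_reactivity(pka, ph + 1.0).lys_re
        assert up == pytest.approx(10.0 * base, rel=1e-9)

    @given(
        pka=st.floats(5.0, 14.0),
        ph=st.floats(3.0, 12.0),
        delta=st.floats(0.01, 3.0),
    )
    def test_monotonicity(self, pka, ph, delta):
        base = triage.lys_reactivity(pka, ph).lys_re
        assert triage.lys_reactivity(pka, ph + delta).lys_re > base
        assert triage.lys_reactivity(pka + delta, ph).lys_re < base

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            triage.lys_reactivity(math.nan, 9.0)


class TestSaltBridges:
    def test_constructed_pair(self, bridge_structure):
        structure, truth = bridge_structure
        bridges = triage.detect_salt_bridges(structure)
        assert len(bridges) == 1
        assert bridges[0].basic_key == ("A", 1, "LYS")
        assert bridges[0].acidic_key == ("A", 2, "ASP")
        assert bridges[0].min_distance == pytest.approx(3.2, abs=1e-9)
        assert truth.bridges[0][2] == pytest.approx(3.2, abs=1e-9)

    def test_beyond_cutoff(self):
        spec = synth.StructureSpec(
            placements=[
                synth.Placement("LYS", 1, "A", (0, 0, 0)),
                synth.Placement("ASP", 2, "A", (8.0, 0, 0)),
            ]
        )
        structure, _ = synth.make_structure(spec)
        assert triage.detect_salt_bridges(structure) == []

    def test_cutoff_is_configurable(self):
        spec = synth.StructureSpec(
            placements=[
                synth.Placement("LYS", 1, "A", (0, 0, 0)),
                synth.Placement("ASP", 2, "A", (5.0, 0, 0)),
            ]
        )
        structure, _ = synth.make_structure(spec)
        assert triage.detect_salt_bridges(structure, cutoff=4.0) == []
        assert len(triage.detect_salt_bridges(structure, cutoff=6.0)) == 1

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        spec = synth.random_structure_spec(
            20, seed=seed, box_size=25.0, min_separation=3.0
        )
        structure, _ = synth.make_structure(spec)
        bridges = triage.detect_salt_bridges(structure)
        oracle = brute_force_bridges(structure)
        assert {(b.basic_key, b.acidic_key) for b in bridges} == set(oracle)
        for b in bridges:
            assert b.min_distance == pytest.approx(
                oracle[(b.basic_key, b.acidic_key)], abs=1e-9
            )

    def test_missing_sidechain_atoms_warns(self):
        text = "\n".join(
            [
                pdb_atom_line(1, "CA", "LYS", "A", 1, 0, 0, 0, element="C"),
                pdb_atom_line(2, "OD1", "ASP", "A", 2, 3, 0, 0, element="O"),
            ]
        )
        structure = sio.parse_pdb(text)
        with pytest.warns(UserWarning, match="lacks side-chain atoms"):
            bridges = triage.detect_salt_bridges(structure)
        assert bridges == []


class TestCrosslinkPairs:
    def _two_lysines(self, separation):
        spec = synth.StructureSpec(
            placements=[
                synth.Placement("LYS", 1, "A", (0, 0, 0)),
                synth.Placement("LYS", 2, "A", (separation, 0, 0)),
            ]
        )
        return synth.make_structure(spec)[0]

    def test_egnhs_span_compatible(self):
        (pair,) = triage.crosslink_pairs(self._two_lysines(12.0))
        assert pair.nz_nz_distance == pytest.approx(12.0)
        assert "EGNHS" in pair.compatible_agents
        assert "GA" not in pair.compatible_agents  # 12 Å > 11 Å span

    def test_out_of_all_spans(self):
        (pair,) = triage.crosslink_pairs(self._two_lysines(25.0))
        assert pair.compatible_agents == ()

    def test_three_lysines_three_pairs(self):
        spec = synth.StructureSpec(
            placements=[
                synth.Placement("LYS", i, "A", (i * 15.0, 0, 0)) for i in (1, 2, 3)
            ]
        )
        structure, _ = synth.make_structure(spec)
        assert len(triage.crosslink_pairs(structure)) == 3

    def test_single_lysine_empty(self):
        spec = synth.StructureSpec(
            placements=[synth.Placement("LYS", 1, "A", (0, 0, 0))]
        )
        structure, _ = synth.make_structure(spec)
        assert triage.crosslink_pairs(structure) == []

    def test_invariant_under_atom_permutation(self):
        structure, _ = synth.make_structure(
            synth.random_structure_spec(12, seed=13, kinds=("LYS", "GLY"))
        )
        shuffled_atoms = list(structure.atoms)
        random.Random(0).shuffle(shuffled_atoms)
        shuffled = sio.ProteinStructure(shuffled_atoms)
        assert triage.crosslink_pairs(structure) == triage.crosslink_pairs(shuffled)

    def test_distances_match_generator_truth(self):
        spec = ring_of_lysines(5, radius=10.0)
        structure, truth = synth.make_structure(spec)
        for pair in triage.crosslink_pairs(structure):
            key = frozenset((pair.lysine_a, pair.lysine_b))
            assert pair.nz_nz_distance == pytest.approx(truth.nz_distances[key])


def run_triage(structure, pka_entries, ph=9.0, cutoff=4.0, threshold=0.20):
    sasa = surf.shrake_rupley(structure)
    exposures = surf.residue_exposure(sasa, threshold=threshold)
    bridges = triage.detect_salt_bridges(structure, cutoff)
    return triage.triage_sites(exposures, pka_entries, bridges, ph)


class TestTriageSites:
    def test_eight_exposed_four_bridged_gives_four_candidates(
        self, eight_lys_structure
    ):
        structure, truth = eight_lys_structure
        profiles = run_triage(structure, {})
        lys_profiles = [p for p in profiles if p.residue_key[2] == "LYS"]
        assert len(lys_profiles) == 8
        assert all(p.exposure_class == "exposed" for p in lys_profiles)
        assert len(truth.bridges) == 4
        candidates = [p for p in lys_profiles if p.candidate]
        assert len(candidates) == 4
        bridged = {b[0] for b in truth.bridges}
        assert {p.residue_key for p in candidates} == {
            k for k in structure.residues_named("LYS") if k not in bridged
        }

    def test_all_buried_zero_candidates(self):
        spec = synth.StructureSpec(
            placements=[
                synth.Placement("LYS", 1, "A", (0, 0, 0), decoy_shell=(30, 2.0)),
                synth.Placement("LYS", 2, "A", (30, 0, 0), decoy_shell=(30, 2.0)),
            ]
        )
        structure, _ = synth.make_structure(spec)
        profiles = run_triage(structure, {})
        assert sum(p.candidate for p in profiles) == 0

    def test_tie_break_lower_residue_number_first(self, eight_lys_structure):
        structure, _ = eight_lys_structure
        pka = {k: 10.4 for k in structure.residues_named("LYS")}
        profiles = run_triage(structure, pka)
        candidates = [p for p in profiles if p.candidate]
        numbers = [p.residue_key[1] for p in candidates]
        assert numbers == sorted(numbers)

    def test_candidates_subset_of_exposed_not_bridged(self):
        for seed in range(5):
            structure, _ = synth.make_structure(
                synth.random_structure_spec(15, seed=seed, box_size=30.0,
                                            min_separation=4.0)
            )
            profiles = run_triage(structure, {})
            for p in profiles:
                if p.candidate:
                    assert p.exposure_class == "exposed"
                    assert not p.in_salt_bridge

    def test_removing_bridge_never_removes_candidate(self, eight_lys_structure):
        structure, _ = eight_lys_structure
        sasa = surf.shrake_rupley(structure)
        exposures = surf.residue_exposure(sasa)
        bridges = triage.detect_salt_bridges(structure)
        full = triage.triage_sites(exposures, {}, bridges, 9.0)
        before = {p.residue_key for p in full if p.candidate}
        fewer = triage.triage_sites(exposures, {}, bridges[1:], 9.0)
        after = {p.residue_key for p in fewer if p.candidate}
        assert before <= after

    def test_ranking_prefers_higher_reactivity(self, eight_lys_structure):
        structure, truth = eight_lys_structure
        bridged = {b[0] for b in truth.bridges}
        free = sorted(k for k in structure.residues_named("LYS") if k not in bridged)
        pka = {k: 10.4 for k in free}
        pka[free[-1]] = 8.9  # strongly downshifted -> should rank first
        profiles = run_triage(structure, pka)
        assert profiles[0].residue_key == free[-1]
        assert profiles[0].reactivity_class == "high"

    def test_missing_pka_flagged_and_ranked_by_exposure(self, eight_lys_structure):
        structure, truth = eight_lys_structure
        bridged = {b[0] for b in truth.bridges}
        free = sorted(k for k in structure.residues_named("LYS") if k not in bridged)
        pka = {k: 10.4 for k in free[:2]}
        profiles = run_triage(structure, pka)
        flagged = [p for p in profiles if not p.has_pka]
        assert len(flagged) == 6
        assert all(p.lys_re is None for p in flagged)
        # pKa-scored candidates come before unscored candidates
        cand = [p for p in profiles if p.candidate]
        scored = [p.has_pka for p in cand]
        assert scored == sorted(scored, reverse=True)

    def test_salt_bridge_partners_recorded(self, bridge_structure):
        structure, _ = bridge_structure
        profiles = run_triage(structure, {})
        (lys,) = [p for p in profiles if p.residue_key[2] == "LYS"]
        assert lys.in_salt_bridge
        assert lys.salt_bridge_partners == [("A", 2, "ASP")]
        assert not lys.candidate

    def test_empty_input_empty_output(self):
        assert triage.triage_sites([], {}, [], 9.0) == []
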