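"""Branch length scores, shuffled controls, precision gating."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from utrcoop.conservation import (
    branch_length_score,
    conserved_species_for_hit,
    count_genome_hits,
    gate_rbp_motif,
    generate_control_motifs,
    motif_similarity,
    precision_curve,
)
from utrcoop.core import PhyloTree, SiteCall, parse_motif_consensus
from utrcoop.simulate import generate_phylogeny

from .conftest import random_rna
from .oracles import spanning_length_bruteforce


class TestBranchLengthScore:
    def test_hand_enumerated_subtree(self, balanced_tree):
        # path Ref-S1 spans their two pendant edges only: 2 of 6
        assert branch_length_score(balanced_tree, {"Ref", "S1"}) == pytest.approx(1 / 3)

    def test_single_leaf_spans_no_edges(self, balanced_tree):
        assert branch_length_score(balanced_tree, {"Ref"}) == 0.0

    def test_all_leaves_span_full_tree(self, balanced_tree):
        assert branch_length_score(balanced_tree, set(balanced_tree.leaves)) == pytest.approx(1.0)

    def test_empty_set_rejected(self, balanced_tree):
        with pytest.raises(ValueError):
            branch_length_score(balanced_tree, set())

    def test_unknown_species_rejected(self, balanced_tree):
        with pytest.raises(ValueError, match="not in tree"):
            branch_length_score(balanced_tree, {"Ref", "S9"})

    @pytest.mark.parametrize("tree_seed", [0, 1, 2])
    def test_matches_union_of_paths_oracle_on_all_subsets(self, tree_seed):
        tree = generate_phylogeny(6, seed=tree_seed)
        newick = tree.as_newick()
        leaves = tree.leaves
        for r in range(2, 7):
            for members in itertools.combinations(leaves, r):
                got = tree.spanning_length(set(members))
                want = spanning_length_bruteforce(newick, set(members))
                assert got == pytest.approx(want, abs=1e-9)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_monotone_under_adding_species(self, seed):
        rng = np.random.default_rng(seed)
        tree = generate_phylogeny(7, seed=int(rng.integers(100)))
        members = {"ref"}
        prev = 0.0
        order = rng.permutation([s for s in tree.leaves if s != "ref"])
        for sp in order:
            members.add(str(sp))
            cur = branch_length_score(tree, members)
            assert cur >= prev - 1e-12
            prev = cur


class TestConservedSpecies:
    def _block(self, block_factory, s1_shift):
        # reference carries UGUAAAUA at position 10; S1's copy is shifted
        L = 60
        bg = "C" * L
        ref = bg[:10] + "UGUAAAUA" + bg[18:]
        s1 = bg[: 10 + s1_shift] + "UGUAAAUA" + bg[18 + s1_shift :]
        s1 = s1[:L]
        rows = {"Ref": ref, "S1": s1, "S2": bg, "S3": bg}
        return block_factory(rows)

    def test_match_within_window_is_conserved(self, block_factory, balanced_tree, pum_motif):
        block = self._block(block_factory, +3)
        hit = SiteCall("tx0", "PUM", 10, 18)
        assert conserved_species_for_hit(block, hit, pum_motif, balanced_tree) == {"Ref", "S1"}

    def test_match_outside_window_not_conserved(self, block_factory, balanced_tree, pum_motif):
        block = self._block(block_factory, +15)
        hit = SiteCall("tx0", "PUM", 10, 18)
        assert conserved_species_for_hit(block, hit, pum_motif, balanced_tree) == {"Ref"}

    def test_distant_hit_rule_drops_farthest(self, block_factory, pum_motif):
        # caterpillar tree: S3 is >2x farther than any other leaf, and both
        # intermediate species (2 of 4 aligned > one-third) lack the motif
        tree = PhyloTree.from_newick(
            "(((Ref:0.1,S1:0.1):0.1,S2:0.3):2.0,S3:4.0);", ref_species="Ref"
        )
        L = 60
        bg = "C" * L
        ref = bg[:10] + "UGUAAAUA" + bg[18:]
        rows = {"Ref": ref, "S1": bg, "S2": bg, "S3": ref}
        block = block_factory(rows)
        hit = SiteCall("tx0", "PUM", 10, 18)
        assert conserved_species_for_hit(block, hit, pum_motif, tree) == {"Ref"}

    def test_distant_hit_kept_when_gap_small(self, block_factory, pum_motif):
        # same topology but the intermediate species also carry the motif
        tree = PhyloTree.from_newick(
            "(((Ref:0.1,S1:0.1):0.1,S2:0.3):2.0,S3:4.0);", ref_species="Ref"
        )
        L = 60
        bg = "C" * L
        ref = bg[:10] + "UGUAAAUA" + bg[18:]
        rows = {"Ref": ref, "S1": ref, "S2": ref, "S3": ref}
        block = block_factory(rows)
        hit = SiteCall("tx0", "PUM", 10, 18)
        got = conserved_species_for_hit(block, hit, pum_motif, tree)
        assert got == {"Ref", "S1", "S2", "S3"}

    def test_species_absent_from_tree_rejected(self, block_factory, balanced_tree, pum_motif):
        rows = {"Ref": "A" * 20, "SX": "A" * 20}
        block = block_factory(rows)
        with pytest.raises(ValueError, match="absent"):
            conserved_species_for_hit(
                block, SiteCall("tx0", "PUM", 0, 8), pum_motif, balanced_tree
            )


class TestMotifSimilarity:
    def test_identity_is_maximal(self):
        m = parse_motif_consensus("UGUA", "a")
        n = parse_motif_consensus("UGAA", "b")
        assert motif_similarity(m, m) == pytest.approx(1.0)
        assert motif_similarity(m, n) <= 1.0

    def test_disjoint_columns_give_zero(self):
        a = parse_motif_consensus("AAAA", "a")
        c = parse_motif_consensus("CCCC", "c")
        assert motif_similarity(a, c) == 0.0

    def test_symmetric(self):
        a = parse_motif_consensus("UGUANAUA", "a")
        b = parse_motif_consensus("AUGUANAU", "b")
        assert motif_similarity(a, b) == pytest.approx(motif_similarity(b, a))


class TestControlMotifs:
    def test_homopolymer_is_ineligible(self):
        m = parse_motif_consensus("UUUUUUU", "polyU")
        res = generate_control_motifs(m, ["ACGUACGUACGU"], seed=0)
        assert not res.eligible
        assert res.motifs == []

    def test_controls_are_anagrams(self, rng):
        m = parse_motif_consensus("UGUANAUA", "PUM")
        utrs = [random_rna(rng, 500) for _ in range(20)]
        res = generate_control_motifs(m, utrs, seed=1)
        assert res.eligible
        assert 3 <= len(res.motifs) <= 10
        for c in res.motifs:
            assert sorted(c.pattern) == sorted(m.pattern)
            assert c.pattern != m.pattern

    def test_fixed_seed_reproducible(self, rng):
        m = parse_motif_consensus("UGUANAUA", "PUM")
        utrs = [random_rna(rng, 300) for _ in range(10)]
        r1 = generate_control_motifs(m, utrs, seed=7)
        r2 = generate_control_motifs(m, utrs, seed=7)
        assert [c.pattern for c in r1.motifs] == [c.pattern for c in r2.motifs]


class TestPrecisionCurve:
    def test_formula_cases(self):
        # canonical 100 hits at BLS>=0, shuffled mean 40 -> precision 0.6
        canon = [0.0] * 100
        ctrl = [[0.0] * 40]
        curve = precision_curve(canon, ctrl)
        assert curve.precision[0] == pytest.approx(0.6)
        # no shuffled hits -> precision 1; shuffled == canonical -> 0
        assert precision_curve(canon, [[]]).precision[0] == pytest.approx(1.0)
        assert precision_curve(canon, [[0.0] * 100]).precision[0] == pytest.approx(0.0)

    def test_counts_non_increasing_and_ref_only_hits_count_at_zero(self):
        curve = precision_curve([None, 0.0, 0.5, 1.0], [[0.2, 0.9]])
        assert curve.canonical_counts[0] == 4  # BLS-None hits count at t=0
        assert all(np.diff(curve.canonical_counts) <= 0)
        assert curve.canonical_counts[-1] == 1

    def test_undefined_precision_marked_absent(self):
        curve = precision_curve([0.1], [[0.9]])
        assert np.isnan(curve.precision[50])  # no canonical hits at t=0.5


class TestGate:
    def _curve(self, precisions, counts):
        canon = np.asarray(counts)
        prec = np.asarray(precisions, dtype=float)
        from utrcoop.conservation import BLS_GRID, PrecisionCurve

        return PrecisionCurve(BLS_GRID, canon, np.zeros(101), np.zeros(101), prec)

    def test_low_precision_fails(self):
        assert not gate_rbp_motif(self._curve([0.5] * 101, [1000] * 101))

    def test_high_precision_with_enough_hits_passes(self):
        prec = [0.0] * 50 + [0.8] * 51
        counts = [1000] * 50 + [50] * 51
        assert gate_rbp_motif(self._curve(prec, counts))

    def test_too_few_hits_fails_even_at_high_precision(self):
        prec = [0.7] * 101
        counts = [8] * 101
        assert not gate_rbp_motif(self._curve(prec, counts))


class TestPlantedConservation:
    def test_measured_bls_equals_planted_subset_score(self, block_factory):
        # motif text copied into exactly {ref, s1}; high mutation elsewhere
        from utrcoop.conservation import annotate_sites_with_bls
        from utrcoop.simulate import SimConfig, generate_dataset

        cfg = SimConfig(
            seed=3,
            n_utrs=12,
            n_species=5,
            n_families=2,
            n_planted=0,
            mirna_sites_per_family=2,
            mutation_rate=1.0,  # saturating: non-subset rows scrambled
            conservation_subset=("ref", "s1"),
            conserved_fraction=1.0,
        )
        ds, truth = generate_dataset(cfg)
        expected = branch_length_score(ds.tree, {"ref", "s1"})
        sites = annotate_sites_with_bls(ds.utrs, ds.motifs[0], ds.tree)
        planted = {
            (r.transcript_id, r.start)
            for r in truth.sites[truth.sites["kind"] == "rbp"].itertuples(index=False)
        }
        checked = 0
        for s in sites:
            if (s.transcript_id, s.start) in planted:
                assert s.bls == pytest.approx(expected, abs=1e-9)
                checked += 1
        assert checked >= 5


class TestPrecisionOnRandomSequence:
    def test_precision_near_zero_without_conservation_signal(self, rng):
        # on fully random sequence a motif is no more frequent than its
        # anagrams: precision at BLS 0 stays near 0
        m = parse_motif_consensus("UGUANAUA", "PUM")
        utrs = [random_rna(rng, 2000) for _ in range(100)]  # 200 kb total
        controls = generate_control_motifs(m, utrs, seed=3)
        assert controls.eligible and len(controls.motifs) >= 5
        canon = [0.0] * count_genome_hits(m, utrs)
        ctrl = [[0.0] * count_genome_hits(c, utrs) for c in controls.motifs]
        curve = precision_curve(canon, ctrl)
        assert abs(curve.precision[0]) < 0.1
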