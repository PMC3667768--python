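"""Folding engines, masking, rescue counts, dinucleotide shuffles."""

from collections import Counter

import numpy as np
import pytest

from utrcoop.core import SiteCall
from utrcoop.structure import (
    compare_rescue_distributions,
    default_engine,
    dinucleotide_shuffle,
    extract_pair_window,
    fold,
    rescue_background,
    rescue_count,
)

from .conftest import random_rna
from .oracles import enumerate_structures, max_pairs_bruteforce


class TestFold:
    def test_polya_is_open(self):
        res = fold("AAAAAAAAAA", engine="fallback")
        assert res.structure == "." * 10
        assert not res.paired.any()

    def test_designed_stem_paired_under_fallback(self):
        # 8 bp stem: UGUAAAUA .. UAUUUACA with an A loop, C flanks
        seq = "CCCCCUGUAAAUAAAAAUAUUUACACCCCC"
        res = fold(seq, engine="fallback")
        n_pairs = res.structure.count("(")
        assert n_pairs == max_pairs_bruteforce(seq)
        assert n_pairs >= 8

    def test_weak_structure_reported_fully_open(self):
        # a single possible pair: fallback pseudo-energy -1 is "open"
        res = fold("AAAACCCAUAAA", engine="fallback")
        assert res.structure == "." * 12

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            fold("", engine="fallback")

    def test_n_positions_never_paired_any_engine(self):
        seq = "GGGGGAAANNNNNNNAAACCCCC"
        for engine in {"fallback", default_engine()}:
            res = fold(seq, engine=engine)
            assert not res.paired[8:15].any()

    @pytest.mark.parametrize("trial", range(4))
    def test_fallback_matches_exhaustive_enumeration_small(self, trial, rng):
        seq = random_rna(np.random.default_rng(100 + trial), 12)
        res = fold(seq, engine="fallback", open_energy=1e9)  # keep raw structure
        got = res.structure.count("(")
        structures = enumerate_structures(seq)
        assert got == max(len(s) for s in structures)


class TestPairWindow:
    def test_flanks_added_and_intervals_relocated(self):
        seq = "A" * 200
        w, riv, miv = extract_pair_window(
            seq, SiteCall("t", "PUM", 100, 108), SiteCall("t", "f|m8", 120, 127)
        )
        assert len(w) == 132 - 95
        assert riv == (5, 13) and miv == (25, 32)

    def test_left_clamp_at_utr_start(self):
        seq = "A" * 200
        w, riv, miv = extract_pair_window(
            seq, SiteCall("t", "PUM", 2, 10), SiteCall("t", "f|m8", 30, 37)
        )
        assert riv == (2, 10) and len(w) == 42

    def test_order_independent(self):
        seq = "A" * 200
        a = extract_pair_window(
            seq, SiteCall("t", "PUM", 100, 108), SiteCall("t", "f", 60, 67)
        )
        assert a[0] == seq[55:113]


class TestRescueCount:
    def test_designed_hairpin_c1_seven_under_fallback(self):
        # stem pairs the PUM site to the reverse-complement 7-nt seed site;
        # C loop/flanks cannot pair with the AU-rich stem, so exhaustive
        # enumeration shows the unique 7-pair maximum pairs the full seed
        seq = "CC" + "UGUAAAUA" + "CCC" + "UAUUUAC" + "CC"
        rbp_iv, mirna_iv = (2, 10), (13, 20)
        structures = enumerate_structures(seq)
        best = max(len(s) for s in structures)
        assert best == 7
        res = rescue_count(seq, rbp_iv, mirna_iv, engine="fallback")
        assert res.c1 == 7
        assert res.c2 == 0  # masking the only partner frees the seed site
        assert res.c == res.c1 == 7

    def test_polya_window_all_zero(self):
        res = rescue_count("A" * 40, (5, 13), (20, 27), engine="fallback")
        assert (res.c1, res.c2, res.c) == (0, 0, 0)

    def test_mask_overlap_with_seed_site_rejected(self):
        with pytest.raises(ValueError, match="mask overlaps"):
            rescue_count("A" * 40, (5, 13), (13, 20), engine="fallback")

    def test_masked_positions_never_paired(self):
        seq = "GGGGGUGUAAAUACCCCCUAUUUACAGGGG"
        res = rescue_count(seq, (5, 13), (18, 26), engine="fallback")
        masked = seq[:4] + "N" * 10 + seq[14:]
        fr = fold(masked, engine="fallback")
        assert not fr.paired[4:14].any()

    def test_vienna_engine_rescues_designed_hairpin(self):
        # long GC-stabilized hairpin whose only partner for the seed site is
        # the RBP site; thermodynamic folding must rescue on masking
        if default_engine() != "vienna":
            pytest.skip("ViennaRNA bindings unavailable")
        rbp = "UGUACAUA"
        seed = "UAUGUACA"
        seq = "GGCGC" + rbp + "GAAA" + seed + "GCGCC"
        riv = (5, 13)
        miv = (5 + 8 + 4, 5 + 8 + 4 + 8)
        res = rescue_count(seq, riv, miv, engine="vienna")
        assert res.c1 >= 6
        assert res.c2 < res.c1
        assert res.c >= 1


class TestDinucleotideShuffle:
    def test_counts_exactly_preserved_on_random_60mers(self):
        rng = np.random.default_rng(7)
        for i in range(1000):
            seq = random_rna(rng, 60)
            out = dinucleotide_shuffle(seq, rng=rng)
            assert len(out) == 60
            assert Counter(out) == Counter(seq)
            assert Counter(zip(out, out[1:])) == Counter(zip(seq, seq[1:]))
            assert out[0] == seq[0] and out[-1] == seq[-1]

    def test_dinucleotide_multiset_example(self):
        out = dinucleotide_shuffle("AAUU", seed=0)
        assert Counter(zip(out, out[1:])) == Counter([("A", "A"), ("A", "U"), ("U", "U")])

    def test_homopolymer_fixed_point(self):
        assert dinucleotide_shuffle("AAAA", seed=3) == "AAAA"

    def test_seed_reproducible(self):
        seq = "ACGUACGGUUACGAUCCGAU"
        assert dinucleotide_shuffle(seq, seed=5) == dinucleotide_shuffle(seq, seed=5)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dinucleotide_shuffle("AC", seed=0)


class TestBackground:
    def _pairs(self):
        seq = "CCUGUAAAUAAAAAUAUUUACACC"
        return [(seq, (2, 10), (14, 22)), ("A" * 30, (2, 10), (16, 24))]

    def test_histogram_totals_equal_pair_count(self):
        bg = rescue_background(self._pairs(), n=4, engine="fallback", seed=1)
        assert bg["mean"].sum() == pytest.approx(2.0)

    def test_all_a_windows_identical_to_real_sd_zero(self):
        pairs = [("A" * 30, (2, 10), (16, 24))] * 3
        bg = rescue_background(pairs, n=5, engine="fallback", seed=2)
        assert bg.loc[bg["bin"] == 0, "mean"].iloc[0] == 3.0
        assert (bg["sd"] == 0).all()

    def test_fixed_seed_identical(self):
        a = rescue_background(self._pairs(), n=3, engine="fallback", seed=9)
        b = rescue_background(self._pairs(), n=3, engine="fallback", seed=9)
        assert a.equals(b)


class TestCompareDistributions:
    def test_identical_distributions_p_one(self):
        res = compare_rescue_distributions([1, 2, 3], [1, 2, 3])
        assert res["two_sided"] == 1.0

    def test_exact_one_sided_enumeration_case(self):
        res = compare_rescue_distributions([5, 6, 7], [0, 0, 1])
        assert res["greater"] == pytest.approx(0.05)  # 1 / C(6,3)

    def test_swapping_inputs_flips_direction(self):
        a, b = [5, 6, 7], [0, 0, 1]
        p_ab = compare_rescue_distributions(a, b)["greater"]
        p_ba = compare_rescue_distributions(b, a)["greater"]
        assert p_ab < 0.1 < p_ba

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compare_rescue_distributions([], [1])
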