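"""Proximal pair counting, identity-permutation nulls, interacting calls."""

import numpy as np
import pandas as pd
import pytest

from utrcoop.colocalization import (
    bh_fdr,
    build_interaction_table,
    call_interacting_mirnas,
    count_colocalized,
    empirical_pvalue,
    pair_gap_and_window,
    permute_mirna_identities,
    proximal_fraction,
    rbp_shuffle_enrichment,
    window_enrichment_matrix,
    _strata,
    _window_matrix,
)
from utrcoop.core import SeedFamily, SiteCall

from .oracles import exact_perm_pvalue


def S(tid, start, end, name="m"):
    return SiteCall(tid, name, start, end)


class TestGapWindow:
    @pytest.mark.parametrize(
        "rbp,mirna,gap,window",
        [
            ((100, 108), (120, 127), 12, 0),
            ((100, 108), (200, 207), 92, 1),
            ((100, 108), (20, 27), 73, -2),
            ((100, 108), (104, 111), 0, 0),  # overlap: gap 0, proximal
            ((100, 108), (45, 52), 48, -1),
        ],
    )
    def test_examples(self, rbp, mirna, gap, window):
        g, w = pair_gap_and_window(S("t", *rbp), S("t", *mirna))
        assert (g, w) == (gap, window)

    def test_window_magnitude_consistent_with_gap(self, rng):
        for _ in range(200):
            a, b = sorted(rng.integers(0, 900, size=2))
            r, m = S("t", a, a + 8), S("t", b + 20, b + 27)
            gap, w = pair_gap_and_window(r, m)
            if w >= 0:
                assert 50 * w <= gap < 50 * (w + 1)
            else:
                assert 50 * (-w - 1) <= gap < 50 * (-w)

    def test_different_transcripts_rejected(self):
        with pytest.raises(ValueError):
            pair_gap_and_window(S("a", 0, 8), S("b", 20, 27))


class TestCounting:
    def test_two_family_sites_in_different_windows(self):
        rbp = [S("t", 100, 108)]
        fam = {"X": [S("t", 118, 125), S("t", 168, 175)]}
        counts = count_colocalized(rbp, fam)
        assert counts == {("X", 0): 1, ("X", 1): 1}

    def test_no_shared_transcripts_gives_zero(self):
        assert count_colocalized([S("a", 0, 8)], {"X": [S("b", 20, 27)]}) == {}

    def test_flanking_rbp_sites_both_counted(self):
        # one miRNA site between two RBP sites: both pairs enumerated
        rbp = [S("t", 100, 108), S("t", 140, 148)]
        fam = {"X": [S("t", 113, 120)]}
        counts = count_colocalized(rbp, fam)
        assert counts[("X", 0)] == 1  # downstream of first
        assert counts[("X", -1)] == 1  # upstream of second
        assert sum(counts.values()) == 2

    def test_max_gap_excludes_distant_pairs(self):
        rbp = [S("t", 0, 8)]
        fam = {"X": [S("t", 600, 607)]}
        assert count_colocalized(rbp, fam) == {}


class TestPermutationNull:
    def test_single_family_null_equals_observed(self):
        rbp = [S("t", 100, 108)]
        sites = [S("t", 120, 127), S("t", 300, 307)]
        M = _window_matrix(rbp, sites)
        labels = np.zeros(2, dtype=np.int64)
        null = permute_mirna_identities(labels, np.zeros(2), M, 1, n=50, seed=0)
        obs = M.sum(axis=0)
        assert np.all(null == obs[None, None, :])

    def test_stratum_label_multisets_preserved(self, rng):
        labels = rng.integers(0, 4, size=40)
        strata = rng.integers(0, 3, size=40)
        M = np.ones((40, 20), dtype=np.int64)
        # total per family over all windows = 20 * (# sites with that label),
        # so per-stratum preservation implies the family counts never change
        null = permute_mirna_identities(labels, strata, M, 4, n=20, seed=1)
        want = 20 * np.bincount(labels, minlength=4)
        assert np.all(null.sum(axis=2) == want[None, :])

    def test_fixed_seed_reproducible(self, rng):
        labels = rng.integers(0, 3, size=25)
        strata = rng.integers(0, 2, size=25)
        M = rng.integers(0, 2, size=(25, 20))
        a = permute_mirna_identities(labels, strata, M, 3, n=10, seed=9)
        b = permute_mirna_identities(labels, strata, M, 3, n=10, seed=9)
        assert np.array_equal(a, b)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown shuffling scheme"):
            _strata("bogus", [], np.array([]), [], {}, "m8", None)

    def test_sampled_p_matches_full_enumeration(self):
        # 5 sites, 2 families, decile-like strata: exhaustive reference
        rng = np.random.default_rng(4)
        labels = np.array([0, 0, 1, 1, 0])
        strata = np.array([0, 0, 0, 1, 1])
        contributes = np.array([1, 0, 1, 1, 0])  # window-0 contribution per site
        M = np.zeros((5, 20), dtype=np.int64)
        M[:, 10] = contributes
        exact = exact_perm_pvalue(list(labels), list(strata), list(contributes), 0)
        n = 4000
        null = permute_mirna_identities(labels, strata, M, 2, n=n, seed=11)
        obs = int(M[labels == 0, 10].sum())
        sampled = empirical_pvalue(obs, null[:, 0, 10])
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(sampled - exact) <= 3 * se + 1e-12


class TestEmpiricalP:
    def test_examples(self):
        assert empirical_pvalue(5, np.array([5, 3, 2, 7])) == 0.5
        assert empirical_pvalue(10, np.array([1, 2, 3])) == 0.0
        assert empirical_pvalue(0, np.array([0, 1, 2])) == 1.0

    def test_add_one_mode_never_zero(self):
        assert empirical_pvalue(10, np.array([1, 2, 3]), mode="add_one") == pytest.approx(
            1 / 4
        )

    def test_no_replicates_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1, np.array([]))


class TestBH:
    def test_step_up_example(self):
        assert bh_fdr([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_equal_and_single(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
        assert bh_fdr([0.7]) == pytest.approx([0.7])

    def test_q_at_least_p(self, rng):
        p = rng.random(50)
        assert np.all(bh_fdr(p) >= p - 1e-12)


def _toy_families(n):
    # designed so every m8 site has 3-5 A/U bases (one shared AU category;
    # a single-family stratum would make the AU-scheme null degenerate)
    from utrcoop.core import reverse_complement

    sites = ["UAUGCAC", "AUCGUAG", "GAUCAUG", "CAUGUCA", "ACUGAUC", "UGACAUG"][:n]
    return [
        SeedFamily.from_mature(f"f{i}", "U" + reverse_complement(s) + "A" * 14)
        for i, s in enumerate(sites)
    ]


class TestCallingAndEnrichment:
    def _table(self, rows):
        cols = ["rbp", "family", "seed_type", "window", "observed"]
        scheme_cols = []
        for s in ("plain", "by_decile", "by_au_category"):
            scheme_cols += [f"null_mean_{s}", f"null_sd_{s}", f"p_{s}", f"q_{s}"]
        return pd.DataFrame(rows, columns=cols + scheme_cols)

    def _row(self, fam, st, w, obs, q):
        return ["PUM", fam, st, w, obs] + [obs / 2, 1.0, q, q] * 3

    def test_first_window_rule(self):
        rows = [self._row("fX", st, w, 10, 0.01 if w in (0,) else 0.5)
                for st in ("m8", "1a") for w in (-1, 0, 3)]
        assert call_interacting_mirnas(self._table(rows)) == {"fX"}
        # enrichment only at window 3 is not called
        rows = [self._row("fY", st, w, 10, 0.01 if w == 3 else 0.5)
                for st in ("m8", "1a") for w in (-1, 0, 3)]
        assert call_interacting_mirnas(self._table(rows)) == set()

    def test_intersection_rule_failing_one_scheme_blocks_call(self):
        rows = []
        for st in ("m8", "1a"):
            r = ["PUM", "fZ", st, 0, 10] + [5, 1, 0.01, 0.01] * 2 + [5, 1, 0.5, 0.5]
            rows.append(r)
        assert call_interacting_mirnas(self._table(rows)) == set()

    def test_both_seed_types_required(self):
        rows = [self._row("fW", "m8", 0, 10, 0.01), self._row("fW", "1a", 0, 10, 0.5)]
        assert call_interacting_mirnas(self._table(rows)) == set()

    def test_window_enrichment_min_rule(self):
        rows = []
        for st in ("m8", "1a"):
            r = ["PUM", "fA", st, 0, 4] + [2, 1, 0.1, 0.1] + [2.5, 1, 0.1, 0.1] + [2.25, 1, 0.1, 0.1]
            rows.append(r)
        mat = window_enrichment_matrix(self._table(rows))
        # pooled observed 8 vs scheme null means {4, 5, 4.5}: min ratio 1.6
        assert mat.loc["fA", 0] == pytest.approx(1.6)

    def test_window_enrichment_zero_guards(self):
        rows = [["PUM", "fB", "m8", 0, 0] + [0, 0, 1, 1] * 3,
                ["PUM", "fC", "m8", 0, 3] + [0, 0, 0.1, 0.1] * 3]
        mat = window_enrichment_matrix(self._table(rows), n_perm=100)
        assert mat.loc["fB", 0] == 1.0
        assert mat.loc["fC", 0] == 300  # capped at observed * n_perm

    def test_planted_cooccurrence_is_called(self):
        # family f0 planted 3x around RBP sites; f1/f2 background
        rng = np.random.default_rng(2)
        fams = _toy_families(3)
        utr_len = {f"t{i}": 1000 for i in range(60)}
        rbp_sites, by_type = [], {"m8": {}, "1a": {}}
        # RBP positions spread along the UTRs so the decile-stratified null
        # cannot attribute the planted proximity to positional preference
        rbp_pos = {i: int(rng.integers(100, 800)) for i in range(60)}
        for i in range(60):
            rbp_sites.append(S(f"t{i}", rbp_pos[i], rbp_pos[i] + 8, "PUM"))
        for fi, fam in enumerate(fams):
            for st in ("m8", "1a"):
                sites = []
                for i in range(60):
                    if fi == 0 and i % 2 == 0:  # planted proximal
                        p = rbp_pos[i] + 8 + int(rng.integers(0, 44))
                        sites.append(S(f"t{i}", p, p + 7, fam.family_id))
                    else:
                        pos = int(rng.integers(0, 900))
                        sites.append(S(f"t{i}", pos, pos + 7, fam.family_id))
                by_type[st][fam.family_id] = sites
        table = build_interaction_table(
            "PUM", rbp_sites, by_type, fams, utr_len, n_perm=1000, seed=5
        )
        called = call_interacting_mirnas(table)
        assert "f0" in called
        assert called <= {"f0"}


class TestRbpShuffleEnrichment:
    def test_plug_in_example(self):
        real_rbp = [S("t%d" % i, 100, 108) for i in range(20)]
        ctrl_rbp = [S("t%d" % i, 300, 308) for i in range(20)]
        fam = {"X": [S("t%d" % i, 120, 127) for i in range(20)]}
        mat = rbp_shuffle_enrichment(real_rbp, ctrl_rbp, fam)
        # real pairs all in window 0; control pairs all in window -4;
        # normalization by identical totals leaves the window ratios NaN/defined
        assert np.isnan(mat.loc["X", 1])

    def test_identical_tables_give_one(self):
        rbp = [S("t", 100, 108)]
        fam = {"X": [S("t", 120, 127), S("t", 260, 267)]}
        mat = rbp_shuffle_enrichment(rbp, rbp, fam)
        vals = mat.loc["X"].dropna()
        assert np.allclose(vals, 1.0)


class TestProximalFraction:
    def test_examples(self):
        rbp = [S("t0", 100, 108)]
        fam = [S("t0", 120, 127)] + [S(f"x{i}", 0, 7) for i in range(49)]
        assert proximal_fraction(fam, rbp) == pytest.approx(2.0)
        assert proximal_fraction(fam, []) == 0.0
        assert proximal_fraction([S("t0", 130, 137)], rbp) == 100.0

    def test_empty_family_flagged(self):
        with pytest.raises(ValueError):
            proximal_fraction([], [S("t", 0, 8)])
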