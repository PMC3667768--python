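"""Branch length scores, shuffled-motif controls and the precision gate.

A motif instance on the reference UTR is "conserved" in a species when that
species' aligned row contains a match whose start maps within +/-10
reference-anchored nucleotides of the reference hit.  The branch length
score (BLS) of the instance is the total branch length of the minimal
phylogenetic subtree connecting the conserved species, as a fraction of the
whole tree.  A single hit in a very distant species can inflate the BLS, so
the most distant conserved species is discarded when (a) the species ranked
between it and the next-nearest conserved species that lack the motif number
more than one-third of the aligned genomes, and (b) its patristic distance
to the reference exceeds twice that of the second-most-distant conserved
species.

Motif eligibility is decided by a precision curve against shuffled controls:
precision(t) = 1 - mean shuffled hit count / canonical hit count, with hits
counted at BLS >= t over a 101-threshold grid; a motif passes when some
threshold has precision >= 0.6 with more than 10 canonical hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Union

import numpy as np
import pandas as pd

from .core import (
    IUPAC,
    RNA_BASES,
    AlignedUTR,
    MotifConsensus,
    PhyloTree,
    SiteCall,
    scan_motif_sites,
)

CONSERVATION_WINDOW = 10  # nt, either direction
BLS_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


def conserved_species_for_hit(
    block: AlignedUTR,
    hit: SiteCall,
    motif: MotifConsensus,
    tree: PhyloTree,
    window: int = CONSERVATION_WINDOW,
) -> Set[str]:
    """Species in which a reference hit is conserved, after the distant-hit rule."""
    ref = block.ref_species
    unknown = set(block.species) - set(tree.leaves)
    if unknown:
        raise ValueError(f"species {sorted(unknown)} absent from tree")
    col2ref = block.column_to_ref()
    conserved = {ref}
    for sp in block.species:
        if sp == ref:
            continue
        seq = block.ungapped(sp)
        matches = scan_motif_sites(seq, motif)
        if not matches:
            continue
        positions = block.row_positions(sp)
        for m in matches:
            anchored = col2ref[positions[m.start]]
            if abs(int(anchored) - hit.start) <= window:
                conserved.add(sp)
                break
    return _apply_distant_hit_rule(conserved, block, tree)


def _apply_distant_hit_rule(
    conserved: Set[str], block: AlignedUTR, tree: PhyloTree
) -> Set[str]:
    ref = block.ref_species
    others = sorted(conserved - {ref}, key=lambda s: tree.distance(ref, s))
    if not others:
        return conserved
    farthest = others[-1]
    d_far = tree.distance(ref, farthest)
    d_second = tree.distance(ref, others[-2]) if len(others) >= 2 else 0.0
    n_aligned = len(block.species)
    gap = [
        sp
        for sp in block.species
        if sp not in conserved and d_second < tree.distance(ref, sp) < d_far
    ]
    if len(gap) > n_aligned / 3 and d_far > 2 * d_second:
        conserved = conserved - {farthest}
    return conserved


def branch_length_score(tree: PhyloTree, species_set: Iterable[str]) -> float:
    """Spanning-subtree branch length of ``species_set`` over the total tree length."""
    members = set(species_set)
    if not members:
        raise ValueError("empty species set")
    return tree.spanning_length(members) / tree.total_length


UTRLike = Union[AlignedUTR, str]


def _ref_seqs(utrs: Sequence[UTRLike]) -> List[str]:
    return [u.ref_seq if isinstance(u, AlignedUTR) else u for u in utrs]


def annotate_sites_with_bls(
    utrs: Sequence[AlignedUTR],
    motif: MotifConsensus,
    tree: PhyloTree,
    window: int = CONSERVATION_WINDOW,
) -> List[SiteCall]:
    """Scan every UTR for the motif and attach a BLS to each hit.

    A hit conserved only in the reference gets BLS 0 (it still counts at
    threshold 0.0).
    """
    out = []
    for u in utrs:
        for hit in scan_motif_sites(u.ref_seq, motif, u.transcript_id):
            sp = conserved_species_for_hit(u, hit, motif, tree, window)
            out.append(hit.with_bls(branch_length_score(tree, sp)))
    return out


def count_genome_hits(motif: MotifConsensus, utrs: Sequence[UTRLike]) -> int:
    return sum(len(scan_motif_sites(s, motif)) for s in _ref_seqs(utrs))


# ---------------------------------------------------------------------------
# motif similarity (Tomtom surrogate) and shuffled controls


def _column_profiles(pattern: str) -> np.ndarray:
    prof = np.zeros((len(pattern), 4))
    for i, c in enumerate(pattern):
        bases = IUPAC[c]
        for b in bases:
            prof[i, RNA_BASES.index(b)] = 1.0 / len(bases)
    return prof


def motif_similarity(m1: MotifConsensus, m2: MotifConsensus, min_overlap: int = 4) -> float:
    """Ungapped sliding column-overlap similarity in [0, 1].

    Per overlapping column the score is sum_b min(p1_b, p2_b) of the
    degenerate-letter base distributions; the motif similarity is the best
    mean column score over all offsets with overlap >= ``min_overlap``.
    Self-similarity is maximal (1.0) because each column overlaps itself
    perfectly.
    """
    p1, p2 = _column_profiles(m1.pattern), _column_profiles(m2.pattern)
    n1, n2 = len(p1), len(p2)
    best = 0.0
    for off in range(-(n2 - min_overlap), n1 - min_overlap + 1):
        lo1, hi1 = max(0, off), min(n1, off + n2)
        if hi1 - lo1 < min_overlap:
            continue
        a = p1[lo1:hi1]
        b = p2[lo1 - off : hi1 - off]
        best = max(best, float(np.minimum(a, b).sum(axis=1).mean()))
    return best


@dataclass
class ControlMotifs:
    """Shuffled-motif control set for one canonical motif."""

    canonical: MotifConsensus
    motifs: List[MotifConsensus]
    eligible: bool
    canonical_hits: int = 0


def generate_control_motifs(
    motif: MotifConsensus,
    utrs: Sequence[UTRLike],
    n_raw: int = 200,
    similarity_cut: float = 0.10,
    hit_tolerance: float = 0.20,
    max_keep: int = 10,
    min_keep: int = 3,
    seed: int = 0,
) -> ControlMotifs:
    """Shuffled (anagram) control motifs with redundancy and hit-count filters.

    ``n_raw`` random letter permutations are drawn; candidates in the top
    ``similarity_cut`` fraction of pairwise similarity to the canonical motif
    or to any retained control are discarded; among the survivors up to
    ``max_keep`` controls are chosen, preferring genome hit counts within
    +/-``hit_tolerance`` of the canonical count.  A motif with fewer than
    ``min_keep`` distinct shuffles (e.g. a homopolymer) is flagged
    ineligible rather than raising.
    """
    rng = np.random.default_rng(seed)
    letters = list(motif.pattern)
    seen, candidates = set(), []
    for _ in range(n_raw):
        perm = "".join(rng.permutation(letters))
        if perm != motif.pattern and perm not in seen:
            seen.add(perm)
            candidates.append(
                MotifConsensus(f"{motif.name}_shuf{len(candidates)}", perm, motif.kind)
            )
    if len(candidates) < min_keep:
        return ControlMotifs(motif, [], eligible=False)

    sims_to_canon = [motif_similarity(motif, c) for c in candidates]
    all_pairs = list(sims_to_canon)
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            all_pairs.append(motif_similarity(candidates[i], candidates[j]))
    threshold = float(np.quantile(all_pairs, 1.0 - similarity_cut))

    survivors: List[MotifConsensus] = []
    for cand, s_canon in zip(candidates, sims_to_canon):
        if s_canon >= threshold:
            continue
        if any(motif_similarity(cand, r) >= threshold for r in survivors):
            continue
        survivors.append(cand)
    if len(survivors) < min_keep:
        # redundancy pruning left too few; fall back to arbitrary distinct
        # shuffles, least similar to the canonical first
        order = np.argsort(sims_to_canon, kind="stable")
        survivors = [candidates[i] for i in order[:max_keep]]

    h0 = count_genome_hits(motif, utrs)
    hits = {c.name: count_genome_hits(c, utrs) for c in survivors}
    preferred = [c for c in survivors if abs(hits[c.name] - h0) <= hit_tolerance * h0]
    chosen = preferred[:max_keep]
    for c in survivors:
        if len(chosen) >= max_keep:
            break
        if c not in chosen:
            chosen.append(c)
    return ControlMotifs(motif, chosen, eligible=True, canonical_hits=h0)


# ---------------------------------------------------------------------------
# precision curve and gate


@dataclass
class PrecisionCurve:
    """Hit counts and precision over the 101-threshold BLS grid."""

    thresholds: np.ndarray
    canonical_counts: np.ndarray
    shuffled_mean: np.ndarray
    shuffled_sd: np.ndarray
    precision: np.ndarray  # NaN where the canonical count is 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "canonical": self.canonical_counts,
                "shuffled_mean": self.shuffled_mean,
                "shuffled_sd": self.shuffled_sd,
                "precision": self.precision,
            }
        )


def _counts_at_thresholds(bls_values: Sequence[Optional[float]]) -> np.ndarray:
    vals = np.array([0.0 if v is None else v for v in bls_values], dtype=float)
    return (vals[None, :] >= BLS_GRID[:, None] - 1e-12).sum(axis=1)


def precision_curve(
    canonical_hits_by_bls: Sequence[Optional[float]],
    shuffled_hits_by_bls: Sequence[Sequence[Optional[float]]],
) -> PrecisionCurve:
    """Precision = 1 - (mean shuffled count)/(canonical count) per threshold."""
    canon = _counts_at_thresholds(canonical_hits_by_bls)
    per_control = np.array(
        [_counts_at_thresholds(h) for h in shuffled_hits_by_bls], dtype=float
    )
    if per_control.size == 0:
        per_control = np.zeros((1, len(BLS_GRID)))
    mean = per_control.mean(axis=0)
    sd = per_control.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(canon > 0, 1.0 - mean / np.maximum(canon, 1e-300), np.nan)
    return PrecisionCurve(BLS_GRID.copy(), canon, mean, sd, prec)


def gate_rbp_motif(
    curve: PrecisionCurve, precision_min: float = 0.6, min_hits: int = 10
) -> bool:
    """Pass iff some threshold has precision >= 0.6 and more than 10 canonical hits."""
    ok = (
        np.nan_to_num(curve.precision, nan=-np.inf) >= precision_min
    ) & (curve.canonical_counts > min_hits)
    return bool(ok.any())


@dataclass
class MotifGateResult:
    motif: MotifConsensus
    controls: ControlMotifs
    curve: Optional[PrecisionCurve]
    passed: bool
    sites: List[SiteCall]  # canonical sites with BLS attached


def evaluate_motif_conservation(
    motif: MotifConsensus,
    utrs: Sequence[AlignedUTR],
    tree: PhyloTree,
    seed: int = 0,
    window: int = CONSERVATION_WINDOW,
    **control_kwargs,
) -> MotifGateResult:
    """Full gating pipeline for one motif: controls, BLS tables, curve, gate."""
    controls = generate_control_motifs(motif, utrs, seed=seed, **control_kwargs)
    sites = annotate_sites_with_bls(utrs, motif, tree, window)
    if not controls.eligible:
        return MotifGateResult(motif, controls, None, False, sites)
    shuffled_bls = [
        [s.bls for s in annotate_sites_with_bls(utrs, c, tree, window)]
        for c in controls.motifs
    ]
    curve = precision_curve([s.bls for s in sites], shuffled_bls)
    return MotifGateResult(motif, controls, curve, gate_rbp_motif(curve), sites)
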