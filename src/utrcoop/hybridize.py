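"""Local-alignment hybridization scores between miRNA seed sites and the
reversed RBP motif.

A miRNA whose 8mer seed-match site can base-pair with the reversed RBP
recognition motif can form a hairpin with a proximal RBP site in the mRNA;
RBP binding would open that hairpin and expose the seed site.  The score is
a Smith-Waterman local alignment where a column "matches" when the two bases
can form an A-U, G-C or G-U pair (in either orientation; a degenerate motif
letter matches when any of its expansions pairs): matches score 2,
mismatches 0, insertions/deletions -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import IUPAC, MotifConsensus, SeedFamily
from .decay import ranksum_p

MATCH = 2
MISMATCH = 0
GAP = -1

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def reverse_consensus(motif: MotifConsensus) -> MotifConsensus:
    """Letter-order reversal; degenerate letters preserved."""
    return motif.reversed()


def bases_pair(seed_base: str, motif_letter: str) -> bool:
    """True when any expansion of the motif letter pairs with the seed base."""
    return any((seed_base, b) in _PAIRS for b in IUPAC[motif_letter])


def seed_8mer(family: SeedFamily) -> str:
    """The family's 8mer site: the 7mer-m8 site followed by the 1A adenosine."""
    return family.m8_site.pattern + "A"


@dataclass
class HybridizationScore:
    family_id: str
    rbp_name: str
    score: int
    alignment: Tuple[str, str]  # (seed row, motif row) with '-' gaps


def hybridization_score(
    seed: str, reversed_motif: MotifConsensus, family_id: str = "", rbp_name: str = ""
) -> HybridizationScore:
    """Best local alignment score of a seed sequence against a reversed motif.

    Ties are broken toward the shortest alignment, then the most 5' one, so
    the reported alignment is deterministic.
    """
    if not seed or not len(reversed_motif.pattern):
        raise ValueError("empty alignment inputs")
    s, m = seed.upper().replace("T", "U"), reversed_motif.pattern
    n1, n2 = len(s), len(m)
    H = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            sub = MATCH if bases_pair(s[i - 1], m[j - 1]) else MISMATCH
            H[i, j] = max(0, H[i - 1, j - 1] + sub, H[i - 1, j] + GAP, H[i, j - 1] + GAP)
    best = int(H.max())
    if best == 0:
        return HybridizationScore(family_id, rbp_name, 0, ("", ""))
    # end cell: among maxima prefer the smallest i+j (shortest, most 5')
    ends = np.argwhere(H == best)
    i, j = min(ends, key=lambda ij: (ij[0] + ij[1], ij[0]))
    rows: Tuple[List[str], List[str]] = ([], [])
    while H[i, j] > 0:
        sub = MATCH if bases_pair(s[i - 1], m[j - 1]) else MISMATCH
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub:
            rows[0].append(s[i - 1])
            rows[1].append(m[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + GAP:
            rows[0].append(s[i - 1])
            rows[1].append("-")
            i -= 1
        else:
            rows[0].append("-")
            rows[1].append(m[j - 1])
            j -= 1
    aln = ("".join(reversed(rows[0])), "".join(reversed(rows[1])))
    return HybridizationScore(family_id, rbp_name, best, aln)


def score_families(
    families: Sequence[SeedFamily], rbp_motif: MotifConsensus
) -> Dict[str, HybridizationScore]:
    rev = reverse_consensus(rbp_motif)
    return {
        f.family_id: hybridization_score(seed_8mer(f), rev, f.family_id, rbp_motif.name)
        for f in families
    }


def score_groups(
    families: Sequence[SeedFamily],
    rbp_motif: MotifConsensus,
    interacting_set: Set[str],
    shuffled_motifs: Sequence[MotifConsensus] = (),
) -> Dict[str, object]:
    """Interacting vs non-interacting score distributions with a rank-sum p.

    When shuffled control motifs are supplied, per-control score histograms
    against the interacting families are summarized as mean +/- sd per score
    bin (real-vs-shuffled comparison view).
    """
    scores = score_families(families, rbp_motif)
    int_scores = [scores[f].score for f in scores if f in interacting_set]
    non_scores = [scores[f].score for f in scores if f not in interacting_set]
    if not int_scores or not non_scores:
        raise ValueError("both interacting and non-interacting groups must be non-empty")
    out: Dict[str, object] = {
        "scores": scores,
        "interacting": int_scores,
        "non_interacting": non_scores,
        "p_two_sided": ranksum_p(int_scores, non_scores),
    }
    if shuffled_motifs:
        int_fams = [f for f in families if f.family_id in interacting_set]
        per_control = []
        for ctrl in shuffled_motifs:
            cs = score_families(int_fams, ctrl)
            per_control.append([cs[f.family_id].score for f in int_fams])
        all_scores = [v for row in per_control for v in row] + int_scores
        bins = np.arange(min(all_scores), max(all_scores) + 1)
        hists = np.array(
            [[row.count(int(b)) for b in bins] for row in per_control], dtype=float
        )
        out["shuffled_histogram"] = pd.DataFrame(
            {
                "score": bins,
                "real": [int_scores.count(int(b)) for b in bins],
                "shuffled_mean": hists.mean(axis=0),
                "shuffled_sd": hists.std(axis=0, ddof=0),
            }
        )
    return out
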