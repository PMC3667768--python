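"""Independent brute-force oracles used to validate the fast implementations.

Each oracle deliberately takes a different computational route from the code
it checks: exhaustive enumeration, union-of-paths graph computations, or
direct combinatorial sums, at sizes where exhaustion is feasible.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence, Set, Tuple

import dendropy
import numpy as np

from utrcoop.core import IUPAC

# ---------------------------------------------------------------------------
# motif scanning: window-by-window degenerate-letter check


def scan_bruteforce(seq: str, pattern: str) -> List[int]:
    hits = []
    L = len(pattern)
    for s in range(len(seq) - L + 1):
        window = seq[s : s + L]
        if all(b != "N" and b in IUPAC[c] for b, c in zip(window, pattern)):
            hits.append(s)
    return hits


# ---------------------------------------------------------------------------
# BLS: union of edges on all pairwise leaf-to-leaf paths


def spanning_length_bruteforce(newick: str, members: Set[str]) -> float:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    # node-to-root edge paths per leaf
    paths: Dict[str, List[int]] = {}
    edge_len: Dict[int, float] = {}
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append(id(node.edge))
            edge_len[id(node.edge)] = node.edge.length or 0.0
            node = node.parent_node
        paths[leaf.taxon.label] = path
    union: Set[int] = set()
    for a, b in itertools.combinations(sorted(members), 2):
        pa, pb = set(paths[a]), set(paths[b])
        union |= pa.symmetric_difference(pb)  # edges on the a-b path
    return sum(edge_len[e] for e in union)


# ---------------------------------------------------------------------------
# maximum base pairing: exhaustive enumeration of non-crossing structures

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def max_pairs_bruteforce(seq: str, min_loop: int = 3) -> int:
    """Maximum number of pairs over all valid (non-crossing) structures."""
    n = len(seq)

    def best(i: int, j: int) -> int:
        # enumerate: position i unpaired, or paired with each legal k
        if j - i <= min_loop:
            return 0
        out = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _PAIRS:
                out = max(out, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return out

    import functools

    cached = functools.lru_cache(maxsize=None)(best)
    try:
        return cached(0, n - 1)
    finally:
        cached.cache_clear()


def enumerate_structures(seq: str, min_loop: int = 3) -> List[Set[Tuple[int, int]]]:
    """All valid non-crossing structures (sets of pairs) of a short sequence."""
    n = len(seq)

    def rec(i: int, j: int) -> List[Set[Tuple[int, int]]]:
        if j - i <= min_loop:
            return [set()]
        out = [s for s in rec(i + 1, j)]
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _PAIRS:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append({(i, k)} | left | right)
        return out

    return rec(0, n - 1)


# ---------------------------------------------------------------------------
# local alignment: enumeration of monotone matchings


def hybridization_bruteforce(seed: str, motif: str, match: int = 2, gap: int = -1) -> int:
    """Best local score over all monotone chains of pairing-compatible
    position pairs; between consecutive chain links the unmatched letters
    align as zero-score mismatch columns plus |di - dj| gap columns."""

    def pairs_ok(sb: str, ml: str) -> bool:
        return any((sb, b) in _PAIRS for b in IUPAC[ml])

    compat = sorted(
        (i, j)
        for i in range(len(seed))
        for j in range(len(motif))
        if pairs_ok(seed[i], motif[j])
    )
    best = 0

    def extend(start: int, li: int, lj: int, score: int, started: bool) -> None:
        nonlocal best
        best = max(best, score)
        for idx in range(start, len(compat)):
            i, j = compat[idx]
            if i > li and j > lj:
                cost = abs((i - li - 1) - (j - lj - 1)) * -gap if started else 0
                extend(idx + 1, i, j, score + match - cost, True)

    extend(0, -(10**6), -(10**6), 0, False)
    return best


# ---------------------------------------------------------------------------
# stratified permutation p-value: full enumeration


def exact_perm_pvalue(
    labels: Sequence[int],
    strata: Sequence[int],
    contributes: Sequence[int],
    target_label: int,
) -> float:
    """P(null count >= observed) over ALL distinct stratified label
    permutations, where a site's contribution to the count is
    ``contributes[site]`` when it carries ``target_label``."""
    labels = list(labels)
    strata = list(strata)
    idx_by_stratum: Dict[int, List[int]] = {}
    for i, s in enumerate(strata):
        idx_by_stratum.setdefault(s, []).append(i)

    def count_for(assign: Sequence[int]) -> int:
        return sum(c for lab, c in zip(assign, contributes) if lab == target_label)

    observed = count_for(labels)
    per_stratum_perms = []
    for s, idxs in idx_by_stratum.items():
        labs = [labels[i] for i in idxs]
        per_stratum_perms.append((idxs, sorted(set(itertools.permutations(labs)))))
    total = ge = 0
    for combo in itertools.product(*[p for _, p in per_stratum_perms]):
        assign = list(labels)
        for (idxs, _), perm in zip(per_stratum_perms, combo):
            for i, lab in zip(idxs, perm):
                assign[i] = lab
        total += 1
        if count_for(assign) >= observed:
            ge += 1
    return ge / total


# ---------------------------------------------------------------------------
# exact binomial upper tail via direct summation


def binom_tail_bruteforce(k: int, n: int, p: float) -> float:
    import math

    return sum(
        math.comb(n, j) * (p**j) * ((1 - p) ** (n - j)) for j in range(k, n + 1)
    )
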