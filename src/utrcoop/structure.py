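"""Secondary-structure rescue of miRNA seed-match sites by RBP binding.

For each proximal RBP-miRNA site pair, the pair window (5 nt beyond the
outermost site edges) is folded; C1 counts seed-site bases engaged in
intramolecular pairs.  The RBP site plus one flanking base on each side is
then masked to N (N can never pair) and the window refolded, giving C2.  The
rescue count C = C1 - C2 estimates how many seed bases RBP binding would
free from structure.  Predicted structures with folding energy above
-1 kcal/mol are treated as fully open.

Two folding engines satisfy the same contract: thermodynamic MFE folding
through the ViennaRNA bindings when importable, and a maximum-base-pairing
(Nussinov-style) engine with minimum hairpin loop 3, A-U/G-C/G-U pairs, and
a pseudo-energy of -1 kcal/mol per pair.  Under the pseudo-energy the open
rule makes single-pair structures open, mirroring its intent.

The background model dinucleotide-shuffles each window (exact mono- and
di-nucleotide count preservation via the Eulerian-walk construction) while
keeping the site intervals fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import SiteCall

try:  # ViennaRNA python bindings (optional engine)
    import RNA as _vienna
except ImportError:  # pragma: no cover
    _vienna = None

OPEN_ENERGY = -1.0  # kcal/mol; structures at or above this are fully open
PAIR_FLANK = 5  # nt added on each side of the pair window
MASK_FLANK = 1  # nt masked on each side of the RBP site
MIN_LOOP = 3  # minimum hairpin loop for the max-pairing engine

_CAN_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


@dataclass
class FoldResult:
    structure: str  # dot-bracket
    energy: float  # kcal/mol (pseudo-energy for the max-pairing engine)
    paired: np.ndarray  # bool per position

    def n_paired(self, start: int, end: int) -> int:
        return int(self.paired[start:end].sum())


def default_engine() -> str:
    return "vienna" if _vienna is not None else "fallback"


def fold(seq: str, engine: str = "auto", open_energy: float = OPEN_ENERGY) -> FoldResult:
    """MFE (or maximum-pairing) structure with the open-structure rule applied."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper().replace("T", "U")
    if engine == "auto":
        engine = default_engine()
    if engine == "vienna":
        if _vienna is None:
            raise RuntimeError("ViennaRNA python bindings not importable")
        structure, energy = _vienna.fold(seq)
    elif engine in ("fallback", "nussinov_fallback"):
        structure, npairs = _max_pairing_structure(seq)
        energy = -1.0 * npairs
    else:
        raise ValueError(f"unknown folding engine {engine!r}")
    if energy >= open_energy:
        structure = "." * len(seq)
    paired = np.frombuffer(structure.encode(), dtype=np.uint8) != ord(".")
    masked_paired = [p and seq[i] != "N" for i, p in enumerate(paired)]
    return FoldResult(structure, float(energy), np.array(masked_paired, dtype=bool))


def _max_pairing_structure(seq: str, min_loop: int = MIN_LOOP) -> Tuple[str, int]:
    """Nussinov maximum base pairing (A-U, G-C, G-U), loop >= ``min_loop``."""
    n = len(seq)
    best = np.zeros((n + 1, n + 1), dtype=np.int32)  # best[i][j], j exclusive

    def can(i: int, j: int) -> bool:
        return (seq[i], seq[j]) in _CAN_PAIR

    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # window [i, j)
            b = best[i + 1, j]
            for k in range(i + min_loop + 1, j):
                if can(i, k):
                    cand = 1 + best[i + 1, k] + best[k + 1, j]
                    if cand > b:
                        b = cand
            best[i, j] = b
    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while j - i > min_loop + 1:
            if best[i, j] == best[i + 1, j]:
                i += 1
                continue
            for k in range(i + min_loop + 1, j):
                if can(i, k) and best[i, j] == 1 + best[i + 1, k] + best[k + 1, j]:
                    structure[i], structure[k] = "(", ")"
                    traceback(i + 1, k)
                    i, j = k + 1, j
                    break
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("traceback failed")

    traceback(0, n)
    return "".join(structure), int(best[0, n])


# ---------------------------------------------------------------------------
# pair windows and rescue counts


def extract_pair_window(
    utr_seq: str,
    rbp_site: SiteCall,
    mirna_site: SiteCall,
    flank: int = PAIR_FLANK,
) -> Tuple[str, Tuple[int, int], Tuple[int, int]]:
    """Window sequence plus the two site intervals in window coordinates.

    The window spans from ``flank`` nt upstream of the 5'-most site to
    ``flank`` nt downstream of the 3'-most site, clamped to the UTR.
    """
    lo = max(0, min(rbp_site.start, mirna_site.start) - flank)
    hi = min(len(utr_seq), max(rbp_site.end, mirna_site.end) + flank)
    if hi <= lo:
        raise ValueError("degenerate pair window")
    rbp_iv = (rbp_site.start - lo, rbp_site.end - lo)
    mirna_iv = (mirna_site.start - lo, mirna_site.end - lo)
    return utr_seq[lo:hi], rbp_iv, mirna_iv


@dataclass
class RescueResult:
    """Seed bases paired before (c1) and after (c2) masking; c = c1 - c2."""

    c1: int
    c2: int

    @property
    def c(self) -> int:
        return self.c1 - self.c2


def rescue_count(
    window_seq: str,
    rbp_iv: Tuple[int, int],
    mirna_iv: Tuple[int, int],
    engine: str = "auto",
    open_energy: float = OPEN_ENERGY,
    mask_flank: int = MASK_FLANK,
) -> RescueResult:
    """Rescue count for one pair window (intervals in window coordinates)."""
    a = max(0, rbp_iv[0] - mask_flank)
    b = min(len(window_seq), rbp_iv[1] + mask_flank)
    if a < mirna_iv[1] and mirna_iv[0] < b:
        raise ValueError("RBP mask overlaps the miRNA site; overlapping pairs unsupported")
    before = fold(window_seq, engine, open_energy)
    c1 = before.n_paired(*mirna_iv)
    masked = window_seq[:a] + "N" * (b - a) + window_seq[b:]
    after = fold(masked, engine, open_energy)
    c2 = after.n_paired(*mirna_iv)
    return RescueResult(c1=c1, c2=c2)


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Eulerian-walk construction)


def dinucleotide_shuffle(
    seq: str, seed: Optional[int] = None, rng: Optional[np.random.Generator] = None
) -> str:
    """Random sequence with exactly the same mono- and di-nucleotide counts.

    Altschul-Erickson construction: the sequence is an Eulerian walk on the
    dinucleotide multigraph; a random last-exit edge tree rooted at the final
    vertex is drawn, the remaining out-edges are shuffled, and the walk is
    replayed.  The first and last letters are preserved.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than 3 nt")
    if rng is None:
        rng = np.random.default_rng(seed)
    edges: Dict[str, List[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)

    def reaches_last(last_edge: Dict[str, str]) -> bool:
        for v in last_edge:
            cur, hops = v, 0
            while cur != last and hops <= len(vertices):
                if cur not in last_edge:
                    return False
                cur = last_edge[cur]
                hops += 1
            if cur != last:
                return False
        return True

    chosen: Optional[Dict[str, str]] = None
    for _ in range(10000):
        cand = {
            v: edges[v][rng.integers(len(edges[v]))] for v in vertices if v != last
        }
        if reaches_last(cand):
            chosen = cand
            break
    if chosen is None:  # original last-exit edges always form a valid tree
        chosen = {}
        for i in range(len(seq) - 1):
            if seq[i] != last:
                chosen[seq[i]] = seq[i + 1]

    walk_lists: Dict[str, List[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v != last and v in chosen:
            pool.remove(chosen[v])
            order = rng.permutation(len(pool))
            pool = [pool[i] for i in order] + [chosen[v]]
        else:
            order = rng.permutation(len(pool))
            pool = [pool[i] for i in order]
        walk_lists[v] = pool

    out = [seq[0]]
    cursor = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = walk_lists[cur][cursor[cur]]
        cursor[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# background model and comparisons

PairWindow = Tuple[str, Tuple[int, int], Tuple[int, int]]


def rescue_counts_for_pairs(
    pair_windows: Sequence[PairWindow], engine: str = "auto"
) -> List[int]:
    return [rescue_count(w, r, m, engine).c for w, r, m in pair_windows]


def rescue_background(
    pair_windows: Sequence[PairWindow],
    n: int = 10,
    engine: str = "auto",
    seed: int = 0,
) -> pd.DataFrame:
    """Histogram mean +/- sd of rescue counts over ``n`` randomizations.

    Each randomization dinucleotide-shuffles every pair window's sequence
    with the site intervals fixed in place, then recomputes all rescue
    counts.  Bins cover the observed integer range.
    """
    rng = np.random.default_rng(seed)
    reps: List[List[int]] = []
    for _ in range(n):
        counts = []
        for w, r, m in pair_windows:
            counts.append(rescue_count(dinucleotide_shuffle(w, rng=rng), r, m, engine).c)
        reps.append(counts)
    all_vals = [c for rep in reps for c in rep]
    lo, hi = (min(all_vals), max(all_vals)) if all_vals else (0, 0)
    bins = np.arange(lo, hi + 1)
    hists = np.array(
        [[rep.count(int(b)) for b in bins] for rep in reps], dtype=float
    )
    return pd.DataFrame(
        {
            "bin": bins,
            "mean": hists.mean(axis=0) if len(reps) else np.zeros_like(bins, float),
            "sd": hists.std(axis=0, ddof=0) if len(reps) else np.zeros_like(bins, float),
        }
    )


def compare_rescue_distributions(
    real_counts: Sequence[float], other_counts: Sequence[float]
) -> Dict[str, float]:
    """Two-sided and one-sided (real greater) rank-sum p-values."""
    if not len(real_counts) or not len(other_counts):
        raise ValueError("both rescue-count collections must be non-empty")
    from .decay import ranksum_p

    return {
        "two_sided": ranksum_p(real_counts, other_counts, "two-sided"),
        "greater": ranksum_p(real_counts, other_counts, "greater"),
    }
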