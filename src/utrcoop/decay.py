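"""Transcript decay and site-conservation comparisons by pairing group.

Transcripts carrying an RBP site are divided into four groups by the
presence and proximity (<= 50 nt) of seed-match sites for expressed
interacting vs non-interacting miRNA families:

* ``Int-proximal``    -- an interacting-family site within 50 nt of an RBP site,
* ``Int-distant``     -- both present on the transcript, never within 50 nt,
* ``Nonint-proximal`` -- only non-interacting family sites, one within 50 nt,
* ``Nonint-distant``  -- only non-interacting family sites, never within 50 nt,

with interacting status taking precedence over non-interacting and proximal
over distant.  Group half-lives (or decay rates) and RBP-site branch length
scores are compared with two-sided Wilcoxon rank-sum tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .colocalization import PROXIMAL_NT, pair_gap_and_window
from .core import SiteCall

GROUPS = ("Int-proximal", "Int-distant", "Nonint-proximal", "Nonint-distant")
HEADLINE_PAIRINGS = (
    ("Int-proximal", "Nonint-proximal"),
    ("Int-proximal", "Int-distant"),
)


def filter_expressed_mirnas(
    expression: Mapping[str, int], quantile: float = 0.25
) -> Set[str]:
    """Families in the top ``quantile`` of read counts; ties at the cutoff
    are all included."""
    if not expression:
        raise ValueError("empty expression table")
    counts = sorted(expression.values(), reverse=True)
    k = max(1, int(np.floor(quantile * len(counts) + 1e-9)))
    cutoff = counts[k - 1]
    return {f for f, c in expression.items() if c >= cutoff}


def _split_sites(
    mirna_sites_by_family: Mapping[str, Sequence[SiteCall]],
    interacting: Set[str],
    expressed: Set[str],
) -> Tuple[Dict[str, List[SiteCall]], Dict[str, List[SiteCall]]]:
    """Expressed interacting / expressed non-interacting sites, per transcript."""
    int_sites: Dict[str, List[SiteCall]] = {}
    non_sites: Dict[str, List[SiteCall]] = {}
    for fam, sites in mirna_sites_by_family.items():
        if fam not in expressed:
            continue
        target = int_sites if fam in interacting else non_sites
        for s in sites:
            target.setdefault(s.transcript_id, []).append(s)
    return int_sites, non_sites


def _has_proximal(
    rbp_sites: Sequence[SiteCall], mirna_sites: Sequence[SiteCall]
) -> bool:
    for r in rbp_sites:
        for m in mirna_sites:
            gap, _ = pair_gap_and_window(r, m)
            if gap <= PROXIMAL_NT:
                return True
    return False


def classify_transcripts_by_pairing(
    rbp_sites: Sequence[SiteCall],
    mirna_sites_by_family: Mapping[str, Sequence[SiteCall]],
    interacting_families: Set[str],
    expressed_families: Set[str],
) -> Dict[str, str]:
    """Four-group assignment per transcript (``unclassified`` otherwise)."""
    rbp_by_tid: Dict[str, List[SiteCall]] = {}
    for r in rbp_sites:
        rbp_by_tid.setdefault(r.transcript_id, []).append(r)
    int_sites, non_sites = _split_sites(
        mirna_sites_by_family, interacting_families, expressed_families
    )
    out: Dict[str, str] = {}
    for tid, rsites in rbp_by_tid.items():
        if tid in int_sites:
            prox = _has_proximal(rsites, int_sites[tid])
            out[tid] = "Int-proximal" if prox else "Int-distant"
        elif tid in non_sites:
            prox = _has_proximal(rsites, non_sites[tid])
            out[tid] = "Nonint-proximal" if prox else "Nonint-distant"
        else:
            out[tid] = "unclassified"
    return out


def _exact_ranksum(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Permutation-exact rank-sum p over all C(n, nx) group splits.

    Mid-ranks handle ties; used for tiny samples where the normal
    approximation (and scipy's tie-free exact path) misbehaves.
    """
    from itertools import combinations

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    obs = ranks[:nx].sum()
    ge = le = total = 0
    for idx in combinations(range(len(pooled)), nx):
        s = ranks[list(idx)].sum()
        total += 1
        ge += s >= obs - 1e-9
        le += s <= obs + 1e-9
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2 * min(ge, le) / total)


_EXACT_LIMIT = 30  # pooled sample size below which the exact path is used


def ranksum_p(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p; mid-ranks for ties.

    Small pooled samples use full permutation enumeration (exact even with
    ties); larger ones use the tie-corrected normal approximation.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(np.unique(np.concatenate([x, y]))) == 1:
        return 1.0  # all observations tied; no evidence either way
    from math import comb

    if len(x) + len(y) <= _EXACT_LIMIT and comb(len(x) + len(y), len(x)) <= 50000:
        return _exact_ranksum(x, y, alternative)
    return float(
        stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic").pvalue
    )


@dataclass
class GroupComparison:
    """Box-plot summaries per group plus rank-sum p-values per pairing."""

    summary: pd.DataFrame  # group, n, median, q25, q75, lo_whisker, hi_whisker
    pvalues: Dict[Tuple[str, str], float]  # NaN when a group has < 2 values
    direction: str = "half_life"  # which way "faster decay" points

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), p in self.pvalues.items():
            rows.append({"group_a": a, "group_b": b, "p": p})
        return pd.DataFrame(rows)


def compare_group_values(
    values_by_group: Mapping[str, Sequence[float]],
    pairings: Sequence[Tuple[str, str]] = HEADLINE_PAIRINGS,
    direction: str = "half_life",
) -> GroupComparison:
    """Medians, quartiles, 1.5xIQR whiskers, and rank-sum tests."""
    rows = []
    for g, vals in values_by_group.items():
        v = np.asarray(vals, float)
        if v.size == 0:
            rows.append({"group": g, "n": 0})
            continue
        q25, med, q75 = np.percentile(v, [25, 50, 75])
        iqr = q75 - q25
        lo = v[v >= q25 - 1.5 * iqr].min()
        hi = v[v <= q75 + 1.5 * iqr].max()
        rows.append(
            {
                "group": g,
                "n": v.size,
                "median": med,
                "q25": q25,
                "q75": q75,
                "lo_whisker": lo,
                "hi_whisker": hi,
            }
        )
    pvals: Dict[Tuple[str, str], float] = {}
    for a, b in pairings:
        va = np.asarray(values_by_group.get(a, []), float)
        vb = np.asarray(values_by_group.get(b, []), float)
        if len(va) < 2 or len(vb) < 2:
            pvals[(a, b)] = float("nan")  # comparison skipped, flagged as NaN
        else:
            pvals[(a, b)] = ranksum_p(va, vb)
    return GroupComparison(pd.DataFrame(rows), pvals, direction)


def group_values(
    assignments: Mapping[str, str], values: Mapping[str, float]
) -> Dict[str, List[float]]:
    """Collect per-transcript values (half-life, decay rate) by group."""
    out: Dict[str, List[float]] = {g: [] for g in GROUPS}
    for tid, g in assignments.items():
        if g in out and tid in values:
            out[g].append(values[tid])
    return out


def au_control_decay_groups(
    rbp_sites: Sequence[SiteCall],
    interacting_sites: Sequence[SiteCall],
    control_rbp_sites: Sequence[SiteCall],
    control_mirna_sites: Sequence[SiteCall],
) -> Dict[str, Set[str]]:
    """Real / miR_control / RBP_control transcript groups.

    Real: real RBP site + real interacting-family site within 50 nt;
    miR_control: real RBP site + shuffled-miRNA-motif site within 50 nt;
    RBP_control: shuffled-RBP-motif site + real interacting site within 50 nt.
    The shuffled motifs are AU-composition-matched anagram controls.
    """
    def proximal_tids(a: Sequence[SiteCall], b: Sequence[SiteCall]) -> Set[str]:
        by_tid: Dict[str, List[SiteCall]] = {}
        for s in a:
            by_tid.setdefault(s.transcript_id, []).append(s)
        hit = set()
        for m in b:
            if m.transcript_id in hit:
                continue
            for r in by_tid.get(m.transcript_id, ()):
                gap, _ = pair_gap_and_window(r, m)
                if gap <= PROXIMAL_NT:
                    hit.add(m.transcript_id)
                    break
        return hit

    return {
        "Real": proximal_tids(rbp_sites, interacting_sites),
        "miR_control": proximal_tids(rbp_sites, control_mirna_sites),
        "RBP_control": proximal_tids(control_rbp_sites, interacting_sites),
    }


def site_conservation_by_group(
    rbp_sites_with_bls: Sequence[SiteCall],
    mirna_sites_by_family: Mapping[str, Sequence[SiteCall]],
    interacting_families: Set[str],
    expressed_families: Set[str],
) -> Dict[str, List[float]]:
    """BLS distributions of RBP *sites* classified by miRNA-site proximity.

    Each RBP site lands in exactly one bucket; interacting beats
    non-interacting and proximal beats distant, mirroring the transcript
    grouping.  Sites on transcripts without any expressed miRNA site are
    dropped.
    """
    int_sites, non_sites = _split_sites(
        mirna_sites_by_family, interacting_families, expressed_families
    )
    out: Dict[str, List[float]] = {g: [] for g in GROUPS}
    for r in rbp_sites_with_bls:
        if r.bls is None:
            continue
        tid = r.transcript_id
        if tid in int_sites:
            prox = _has_proximal([r], int_sites[tid])
            out["Int-proximal" if prox else "Int-distant"].append(r.bls)
        elif tid in non_sites:
            prox = _has_proximal([r], non_sites[tid])
            out["Nonint-proximal" if prox else "Nonint-distant"].append(r.bls)
    return out
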