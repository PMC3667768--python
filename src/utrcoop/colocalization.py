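"""Proximal co-occurrence of RBP and miRNA seed-match sites.

For each (RBP, miRNA family) pair, miRNA sites are counted in ten 50-nt
windows upstream (-10..-1) and downstream (0..9) of every RBP site on the
same transcript.  The null keeps every site position fixed and permutes only
the family identities, under three stratifications:

* ``plain``       -- within chromosome (for synthetic data, one stratum per
                     transcript batch, configurable),
* ``by_decile``   -- within the 3'UTR decile holding the site,
* ``by_au_category`` -- within seed AU-content strata (6-7 | 3-5 | 0-2 A/U
                     among the seven seed-match bases).

Empirical p-values (proportion of null counts >= observed) are corrected by
Benjamini-Hochberg per (scheme, seed type, window) batch, and a family is
called an "interacting miRNA" when both seed-match types (m8 and 1A) pass
FDR <= 0.05 under all three schemes in the first 50-nt window on either
side of the RBP site.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import SeedFamily, SiteCall
from .localization import decile_index

PROXIMAL_NT = 50
MAX_GAP = 500
WINDOWS = list(range(-10, 10))  # signed 50-nt windows
SCHEMES = ("plain", "by_decile", "by_au_category")


def pair_gap_and_window(rbp_site: SiteCall, mirna_site: SiteCall) -> Tuple[int, int]:
    """Edge-to-edge gap and signed 50-nt window index for one site pair.

    Negative windows mean the miRNA site is upstream of the RBP site;
    overlapping sites get gap 0 (and count as proximal).
    """
    if rbp_site.transcript_id != mirna_site.transcript_id:
        raise ValueError("sites on different transcripts")
    if mirna_site.start >= rbp_site.start:  # miRNA downstream (or overlapping)
        gap = max(0, mirna_site.start - rbp_site.end)
        window = gap // PROXIMAL_NT
    else:
        gap = max(0, rbp_site.start - mirna_site.end)
        window = -(gap // PROXIMAL_NT) - 1
    return gap, window


def count_colocalized(
    rbp_sites: Sequence[SiteCall],
    mirna_sites_by_family: Mapping[str, Sequence[SiteCall]],
    max_gap: int = MAX_GAP,
) -> Dict[Tuple[str, int], int]:
    """Observed pair counts per (family, window); every pair with gap <
    ``max_gap`` contributes once."""
    by_tid: Dict[str, List[SiteCall]] = {}
    for r in rbp_sites:
        by_tid.setdefault(r.transcript_id, []).append(r)
    counts: Dict[Tuple[str, int], int] = {}
    for fam, sites in mirna_sites_by_family.items():
        for m in sites:
            for r in by_tid.get(m.transcript_id, ()):
                gap, w = pair_gap_and_window(r, m)
                if gap < max_gap:
                    key = (fam, w)
                    counts[key] = counts.get(key, 0) + 1
    return counts


def _window_matrix(
    rbp_sites: Sequence[SiteCall],
    mirna_sites: Sequence[SiteCall],
    max_gap: int = MAX_GAP,
) -> np.ndarray:
    """Per-miRNA-site window contribution matrix, shape (n_sites, 20).

    Column ``w + 10`` holds the number of RBP sites pairing with the site in
    signed window ``w`` at gap < ``max_gap``.  Permuting family labels leaves
    this matrix untouched, which is what makes the identity-permutation null
    cheap.
    """
    by_tid: Dict[str, List[SiteCall]] = {}
    for r in rbp_sites:
        by_tid.setdefault(r.transcript_id, []).append(r)
    M = np.zeros((len(mirna_sites), len(WINDOWS)), dtype=np.int64)
    for i, m in enumerate(mirna_sites):
        for r in by_tid.get(m.transcript_id, ()):
            gap, w = pair_gap_and_window(r, m)
            if gap < max_gap:
                M[i, w + 10] += 1
    return M


def _strata(
    scheme: str,
    mirna_sites: Sequence[SiteCall],
    labels: np.ndarray,
    families: Sequence[SeedFamily],
    utr_lengths: Mapping[str, int],
    seed_type: str,
    chrom_map: Optional[Mapping[str, str]],
) -> np.ndarray:
    if scheme == "plain":
        if chrom_map is None:
            return np.zeros(len(mirna_sites), dtype=np.int64)
        chroms = sorted({chrom_map[s.transcript_id] for s in mirna_sites})
        idx = {c: i for i, c in enumerate(chroms)}
        return np.array([idx[chrom_map[s.transcript_id]] for s in mirna_sites])
    if scheme == "by_decile":
        return np.array(
            [decile_index(s.start, utr_lengths[s.transcript_id]) for s in mirna_sites]
        )
    if scheme == "by_au_category":
        cats = np.array(
            [_au_category(f, seed_type) for f in families], dtype=np.int64
        )
        return cats[labels]
    raise ValueError(f"unknown shuffling scheme {scheme!r}")


def _au_category(family: SeedFamily, seed_type: str) -> int:
    site = family.m8_site if seed_type == "m8" else family.a1_site
    au = sum(1 for c in site.pattern if c in "AU")
    if au >= 6:
        return 0
    if au >= 3:
        return 1
    return 2


def permute_mirna_identities(
    labels: np.ndarray,
    strata: np.ndarray,
    M: np.ndarray,
    n_families: int,
    n: int = 10000,
    seed: int = 0,
) -> np.ndarray:
    """Null count tables, shape (n, n_families, 20).

    Site positions (rows of ``M``) are fixed; family labels are permuted
    within each stratum, preserving per-stratum label multisets.
    """
    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    out = np.zeros((n, n_families, M.shape[1]), dtype=np.int64)
    perm = labels.copy()
    for r in range(n):
        for g in groups:
            perm[g] = labels[g][rng.permutation(len(g))]
        for w in range(M.shape[1]):
            col = M[:, w]
            if col.any():
                out[r, :, w] = np.bincount(perm, weights=col, minlength=n_families)
    return out


def empirical_pvalue(
    observed: float, null_counts: np.ndarray, mode: str = "raw"
) -> float:
    """Proportion of null replicates with a count >= the observed count.

    ``mode='add_one'`` applies (k+1)/(n+1) smoothing so p is never exactly 0
    (raw zeros make BH degenerate).
    """
    n = len(null_counts)
    if n == 0:
        raise ValueError("need at least one null replicate")
    k = int((null_counts >= observed).sum())
    if mode == "raw":
        return k / n
    if mode == "add_one":
        return (k + 1) / (n + 1)
    raise ValueError(f"unknown p-value mode {mode!r}")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# full interaction table


def build_interaction_table(
    rbp_name: str,
    rbp_sites: Sequence[SiteCall],
    sites_by_type: Mapping[str, Mapping[str, Sequence[SiteCall]]],
    families: Sequence[SeedFamily],
    utr_lengths: Mapping[str, int],
    n_perm: int = 10000,
    seed: int = 0,
    schemes: Sequence[str] = SCHEMES,
    chrom_map: Optional[Mapping[str, str]] = None,
    pvalue_mode: str = "raw",
) -> pd.DataFrame:
    """Observed counts, per-scheme nulls, p- and q-values for one RBP.

    ``sites_by_type`` maps seed type ("m8"/"1a") to {family_id: sites}.
    Returns a long-form frame with one row per (family, seed_type, window)
    and per-scheme columns null_mean_*, null_sd_*, p_*, q_*.
    """
    fam_ids = [f.family_id for f in families]
    fam_index = {fid: i for i, fid in enumerate(fam_ids)}
    frames = []
    for t, (seed_type, by_family) in enumerate(sorted(sites_by_type.items())):
        sites: List[SiteCall] = []
        labels: List[int] = []
        for fid, ss in by_family.items():
            for s in ss:
                sites.append(s)
                labels.append(fam_index[fid])
        labels_arr = np.array(labels, dtype=np.int64)
        M = _window_matrix(rbp_sites, sites)
        observed = np.zeros((len(fam_ids), len(WINDOWS)), dtype=np.int64)
        for w in range(len(WINDOWS)):
            if M[:, w].any():
                observed[:, w] = np.bincount(
                    labels_arr, weights=M[:, w], minlength=len(fam_ids)
                )
        df = pd.DataFrame(
            {
                "rbp": rbp_name,
                "family": np.repeat(fam_ids, len(WINDOWS)),
                "seed_type": seed_type,
                "window": np.tile(WINDOWS, len(fam_ids)),
                "observed": observed.ravel(),
            }
        )
        for si, scheme in enumerate(schemes):
            strata = _strata(
                scheme, sites, labels_arr, families, utr_lengths, seed_type, chrom_map
            )
            null = permute_mirna_identities(
                labels_arr,
                strata,
                M,
                len(fam_ids),
                n=n_perm,
                seed=seed * 1009 + 17 * t + si,
            )
            mean = null.mean(axis=0)
            sd = null.std(axis=0, ddof=0)
            pmat = np.zeros_like(observed, dtype=float)
            for fi in range(len(fam_ids)):
                for w in range(len(WINDOWS)):
                    pmat[fi, w] = empirical_pvalue(
                        observed[fi, w], null[:, fi, w], mode=pvalue_mode
                    )
            qmat = np.ones_like(pmat)
            for w in range(len(WINDOWS)):
                qmat[:, w] = bh_fdr(pmat[:, w])
            df[f"null_mean_{scheme}"] = mean.ravel()
            df[f"null_sd_{scheme}"] = sd.ravel()
            df[f"p_{scheme}"] = pmat.ravel()
            df[f"q_{scheme}"] = qmat.ravel()
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def call_interacting_mirnas(
    table: pd.DataFrame,
    fdr: float = 0.05,
    schemes: Sequence[str] = SCHEMES,
    first_windows: Sequence[int] = (0, -1),
) -> Set[str]:
    """Families passing FDR under all schemes, both seed types, first window.

    The upstream (-1) and downstream (0) windows are evaluated separately;
    a seed type qualifies if it passes in either, and a family is called
    when both of its seed types qualify.
    """
    called: Set[str] = set()
    qcols = [f"q_{s}" for s in schemes]
    for fam, sub in table.groupby("family"):
        ok_types = []
        for _, type_sub in sub.groupby("seed_type"):
            first = type_sub[type_sub["window"].isin(first_windows)]
            passes = ((first[qcols] <= fdr).all(axis=1)).any()
            ok_types.append(bool(passes))
        if ok_types and all(ok_types):
            called.add(str(fam))
    return called


def window_enrichment_matrix(
    table: pd.DataFrame,
    schemes: Sequence[str] = SCHEMES,
    n_perm: int = 10000,
) -> pd.DataFrame:
    """Heatmap-ready (family x window) enrichment, min ratio over schemes.

    observed/null_mean per scheme; null mean 0 with observed 0 gives 1, null
    mean 0 with observed > 0 is capped at observed * n_perm.  Both seed
    types are pooled by summing counts.
    """
    agg: Dict[str, pd.DataFrame] = {}
    pooled = table.groupby(["family", "window"], as_index=False).agg(
        {"observed": "sum", **{f"null_mean_{s}": "sum" for s in schemes}}
    )
    ratios = []
    for _, row in pooled.iterrows():
        per_scheme = []
        for s in schemes:
            mu = row[f"null_mean_{s}"]
            obs = row["observed"]
            if mu == 0:
                per_scheme.append(1.0 if obs == 0 else obs * n_perm)
            else:
                per_scheme.append(obs / mu)
        ratios.append(min(per_scheme))
    pooled["ratio"] = ratios
    return pooled.pivot(index="family", columns="window", values="ratio")


def rbp_shuffle_enrichment(
    real_rbp_sites: Sequence[SiteCall],
    control_rbp_sites: Sequence[SiteCall],
    mirna_sites_by_family: Mapping[str, Sequence[SiteCall]],
) -> pd.DataFrame:
    """Real-vs-shuffled-RBP window enrichment, AU-content control.

    ratio = (real/control pairs in window) / (real/control pairs over all
    windows); zero denominators are reported as NaN.
    """
    real = count_colocalized(real_rbp_sites, mirna_sites_by_family)
    ctrl = count_colocalized(control_rbp_sites, mirna_sites_by_family)
    fams = sorted(mirna_sites_by_family)
    out = pd.DataFrame(index=fams, columns=WINDOWS, dtype=float)
    for fam in fams:
        tot_r = sum(real.get((fam, w), 0) for w in WINDOWS)
        tot_c = sum(ctrl.get((fam, w), 0) for w in WINDOWS)
        for w in WINDOWS:
            r, c = real.get((fam, w), 0), ctrl.get((fam, w), 0)
            if c == 0 or tot_c == 0 or tot_r == 0:
                out.loc[fam, w] = np.nan
            else:
                out.loc[fam, w] = (r / c) / (tot_r / tot_c)
    return out


def proximal_fraction(
    family_sites: Sequence[SiteCall],
    rbp_sites: Sequence[SiteCall],
    proximal_nt: int = PROXIMAL_NT,
) -> float:
    """Percentage of a family's sites with some RBP site at gap <= 50 nt."""
    if not family_sites:
        raise ValueError("family has no sites")
    by_tid: Dict[str, List[SiteCall]] = {}
    for r in rbp_sites:
        by_tid.setdefault(r.transcript_id, []).append(r)
    n_prox = 0
    for m in family_sites:
        for r in by_tid.get(m.transcript_id, ()):
            gap, _ = pair_gap_and_window(r, m)
            if gap <= proximal_nt:
                n_prox += 1
                break
    return 100.0 * n_prox / len(family_sites)
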