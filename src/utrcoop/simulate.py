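"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates the genome-scale inputs the analysis was designed
for: a phylogeny over N species, multi-species 3'UTR alignments with an
AU-content gradient toward the 3' end and planted evolutionarily conserved
RBP motif instances, miRNA seed-match sites with a controllable excess of
proximal placement next to RBP sites for a chosen set of "planted
interacting" families, half-lives with a multiplicative effect on
transcripts carrying a planted proximal pair, and Zipf-skewed miRNA read
counts.

Planted motifs are inserted, not selected from background, so ground truth
is exact; background occurrences of the same patterns are still found by
scanning and are part of what the analysis sees.  Species rows evolve from
the reference by independent-site substitution (no indels), so alignment
columns map one-to-one and conservation is controlled purely by where motif
text is copied verbatim.

Default sizes (400 UTRs, 8 species, 50 families, 5 planted interacting
families at 3x proximal excess, half-life multiplier 0.7) are the reference
conditions for planted-signal recovery; a null dataset is the same
configuration with ``n_planted=0`` and ``halflife_effect=1.0``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as uio
from .core import (
    AlignedUTR,
    MotifConsensus,
    PhyloTree,
    SeedFamily,
    parse_motif_consensus,
    reverse_complement,
    scan_motif_sites,
)

_BASES = np.array(list("ACGU"))
_IDX = {b: i for i, b in enumerate("ACGU")}

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _pairing_partners(letter: str) -> str:
    """Bases that can pair (A-U, G-C, G-U) with some expansion of a letter."""
    from .core import IUPAC

    return "".join(
        b for b in "ACGU" if any((b, x) in _PAIRS for x in IUPAC[letter])
    )


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the reference conditions."""

    seed: int = 0
    n_species: int = 8
    n_utrs: int = 400
    utr_log_mean: float = 7.0  # log-normal length, median ~1100 nt
    utr_log_sigma: float = 0.45
    utr_min_len: int = 150
    utr_max_len: int = 6000
    au_gradient: Tuple[float, float] = (0.45, 0.70)  # AU fraction 5' -> 3'
    rbp_motifs: Tuple[Tuple[str, str], ...] = (("PUM", "UGUANAUA"),)
    rbp_sites_per_utr: float = 1.2  # Poisson mean per UTR per motif
    conserved_fraction: float = 0.9  # planted RBP sites copied into the subset
    conservation_subset: Optional[Tuple[str, ...]] = None  # None = all species
    positional_bias: Optional[Tuple[float, ...]] = None  # 10 decile weights
    mutation_rate: float = 0.25  # substitution prob per unit branch length
    tree_scale: float = 0.6
    n_families: int = 50
    n_planted: int = 5
    mirna_sites_per_family: int = 60  # per seed type (m8 and 1A separately)
    colocalization_excess: float = 3.0  # planted proximal rate / baseline
    halflife_effect: float = 0.7  # multiplier for planted-proximal transcripts
    halflife_log_mean: float = 1.8  # log-hours, median ~6 h
    halflife_log_sigma: float = 0.6
    expression_skew: float = 1.1  # Zipf exponent for read counts
    seed_complementarity: bool = True  # planted seeds pair with reversed motif

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.colocalization_excess <= 0 or self.halflife_effect <= 0:
            raise ValueError("rates and multipliers must be positive")
        if self.positional_bias is not None:
            w = np.asarray(self.positional_bias, float)
            if len(w) != 10 or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("positional_bias must be 10 weights summing to 1")


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """The reference conditions with no planted signal."""
    return SimConfig(seed=seed, n_planted=0, halflife_effect=1.0, **overrides)


# ---------------------------------------------------------------------------
# phylogeny


def generate_phylogeny(
    n_species: int, seed: int = 0, tree_scale: float = 0.6
) -> PhyloTree:
    """Random Kingman-coalescent topology with positive branch lengths.

    Leaves are ``ref, s1, .., s{n-1}``; the reference is the first leaf.
    Deterministic per seed (newick text reproduces exactly).
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    names = ["ref"] + [f"s{i}" for i in range(1, n_species)]
    lineages: List[Tuple[str, float]] = [(n, 0.0) for n in names]
    height = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        height += rng.exponential(2.0 / (k * (k - 1))) * tree_scale
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha), (nb, hb) = lineages[i], lineages[j]
        merged = f"({na}:{height - ha:.6f},{nb}:{height - hb:.6f})"
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append((merged, height))
    return PhyloTree.from_newick(lineages[0][0] + ";", ref_species="ref")


# ---------------------------------------------------------------------------
# reference sequences and mutation


def _draw_background(L: int, au: Tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Index array for a random sequence with a linear AU gradient."""
    pos = np.linspace(au[0], au[1], L)
    is_au = rng.random(L) < pos
    half = rng.random(L) < 0.5
    # A=0 C=1 G=2 U=3
    out = np.where(is_au, np.where(half, 0, 3), np.where(half, 1, 2))
    return out.astype(np.int8)


def _mutate(idx: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    hit = rng.random(len(idx)) < p
    shift = rng.integers(1, 4, size=len(idx))
    out = idx.copy()
    out[hit] = (out[hit] + shift[hit]) % 4
    return out


_BASE_BYTES = np.frombuffer(b"ACGU", dtype=np.uint8)


def _to_seq(idx: np.ndarray) -> str:
    return _BASE_BYTES[idx].tobytes().decode()


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    """Resolve degenerate letters to concrete bases."""
    from .core import IUPAC

    return "".join(
        c if len(IUPAC[c]) == 1 else sorted(IUPAC[c])[rng.integers(len(IUPAC[c]))]
        for c in pattern
    )


def _free_slot(
    occupied: List[Tuple[int, int]], start: int, length: int, L: int
) -> bool:
    if start < 0 or start + length > L:
        return False
    return all(start + length <= a or b <= start for a, b in occupied)


# ---------------------------------------------------------------------------
# stage 1: aligned UTRs with planted conserved RBP motifs


@dataclass
class UtrDraft:
    """Mutable per-UTR state used while planting (reference row only)."""

    transcript_id: str
    ref: np.ndarray  # int8 base indices
    occupied: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.ref)

    def paste(self, start: int, text: str) -> None:
        self.ref[start : start + len(text)] = [_IDX[c] for c in text]
        self.occupied.append((start, start + len(text)))


def _draw_position(
    draft: UtrDraft,
    length: int,
    rng: np.random.Generator,
    weights: Optional[Sequence[float]],
    tries: int = 30,
) -> Optional[int]:
    L = draft.length
    for _ in range(tries):
        if weights is None:
            start = int(rng.integers(0, max(1, L - length)))
        else:
            d = int(rng.choice(10, p=np.asarray(weights)))
            lo = L * d // 10
            hi = max(lo + 1, min(L * (d + 1) // 10, L - length))
            start = int(rng.integers(lo, hi))
        if _free_slot(draft.occupied, start, length, L):
            return start
    return None


def _plant_rbp_sites(
    drafts: Sequence[UtrDraft], cfg: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for name, pattern in cfg.rbp_motifs:
        motif = parse_motif_consensus(pattern, name)
        for draft in drafts:
            for _ in range(rng.poisson(cfg.rbp_sites_per_utr)):
                start = _draw_position(draft, len(motif), rng, cfg.positional_bias)
                if start is None:
                    continue
                text = _instantiate(motif.pattern, rng)
                draft.paste(start, text)
                rows.append(
                    {
                        "transcript_id": draft.transcript_id,
                        "start": start,
                        "end": start + len(text),
                        "name": name,
                        "kind": "rbp",
                        "conserved": bool(rng.random() < cfg.conserved_fraction),
                        "proximal": False,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "start", "end", "name", "kind", "conserved", "proximal"],
    )


def _build_rows(
    drafts: Sequence[UtrDraft],
    rbp_truth: pd.DataFrame,
    tree: PhyloTree,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> List[AlignedUTR]:
    subset = (
        set(cfg.conservation_subset)
        if cfg.conservation_subset is not None
        else set(tree.leaves)
    )
    truth_by_tid: Dict[str, List[Tuple[int, int]]] = {}
    if len(rbp_truth):
        for r in rbp_truth.itertuples(index=False):
            if r.conserved:
                truth_by_tid.setdefault(r.transcript_id, []).append((r.start, r.end))
    utrs = []
    for draft in drafts:
        rows = {"ref": _to_seq(draft.ref)}
        for sp in tree.leaves:
            if sp == "ref":
                continue
            p = min(0.75, cfg.mutation_rate * tree.distance("ref", sp))
            mut = _mutate(draft.ref, p, rng)
            if sp in subset:
                for a, b in truth_by_tid.get(draft.transcript_id, ()):
                    mut[a:b] = draft.ref[a:b]
            rows[sp] = _to_seq(mut)
        utrs.append(AlignedUTR(draft.transcript_id, "ref", rows))
    return utrs


def generate_utr_alignments(
    cfg: SimConfig,
    tree: Optional[PhyloTree] = None,
    rng: Optional[np.random.Generator] = None,
    build_rows: bool = True,
) -> Tuple[List[AlignedUTR], pd.DataFrame, List[UtrDraft], PhyloTree]:
    """Aligned UTRs with planted conserved RBP motif instances.

    Returns (utrs, rbp_truth, drafts, tree); the drafts keep the mutable
    reference rows so that a miRNA site plan can still be applied (with
    ``build_rows=False`` the species rows are deferred until then).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    tree = generate_phylogeny(cfg.n_species, cfg.seed, cfg.tree_scale) if tree is None else tree
    lengths = np.clip(
        np.exp(rng.normal(cfg.utr_log_mean, cfg.utr_log_sigma, cfg.n_utrs)),
        cfg.utr_min_len,
        cfg.utr_max_len,
    ).astype(int)
    drafts = [
        UtrDraft(f"tx{i:04d}", _draw_background(int(L), cfg.au_gradient, rng))
        for i, L in enumerate(lengths)
    ]
    rbp_truth = _plant_rbp_sites(drafts, cfg, rng)
    utrs = _build_rows(drafts, rbp_truth, tree, cfg, rng) if build_rows else []
    return utrs, rbp_truth, drafts, tree


# ---------------------------------------------------------------------------
# stage 2: families, miRNA site plan, half-lives, expression


def _overlaps_motif(site8: str, motif_patterns: Sequence[str], min_overlap: int = 5) -> bool:
    """True when a family's seed-match patterns could be spawned by RBP
    motif text.

    A seed-match site is created by an RBP instance when the site pattern
    overlaps the motif with every overlapping position admitted by the
    motif's degenerate letters (the few bases hanging outside the instance
    are completed by background at ~4^-k per instance).  Such families would
    gain co-localization counts from literal overlap with planted RBP
    sites, corrupting the planted/non-planted ground truth, so the
    generator rejects them.  Both derived patterns (m8 and 1A) are checked.
    """
    from .core import IUPAC

    probes = {site8, site8[:7], site8[1:7] + "A"}
    for pattern in motif_patterns:
        for site in probes:
            for off in range(-(len(site) - 1), len(pattern)):
                overlap = [
                    (c, pattern[i + off])
                    for i, c in enumerate(site)
                    if 0 <= i + off < len(pattern)
                ]
                if len(overlap) >= min_overlap and all(
                    c in IUPAC[p] for c, p in overlap
                ):
                    return True
    return False


def _design_complementary_site(
    motif_pattern: str,
    rng: np.random.Generator,
    used: Set[str],
    avoid_patterns: Sequence[str] = (),
) -> Optional[str]:
    """An 8mer ending in A whose bases pair position-wise with the reversed
    motif (hairpin-competent seed site), avoiding near-identity with the
    motif itself."""
    rev = motif_pattern[::-1][:8]
    candidates: List[str] = []
    partners_per_pos = []
    for i, c in enumerate(rev):
        if i == 7:
            partners_per_pos.append("A")  # the 1A adenosine
            continue
        partners = _pairing_partners(c)
        if not partners:
            return None
        partners_per_pos.append(partners)
    from itertools import product

    for combo in product(*partners_per_pos):
        s = "".join(combo)
        if len(s) < 8:
            s = s + "A" * (8 - len(s))
        if s.endswith("A") and s not in used:
            candidates.append(s)
    clean = [s for s in candidates if not _overlaps_motif(s, avoid_patterns)]
    pool = clean or candidates
    if not pool:
        return None
    return pool[rng.integers(len(pool))]


def generate_families(cfg: SimConfig, rng: np.random.Generator) -> List[SeedFamily]:
    """Random 22-nt mature miRNAs with unique m8 site patterns.

    When ``seed_complementarity`` is on, the planted families' 8mer sites
    are designed to base-pair with the reversed first RBP motif, the
    mechanism that lets a proximal RBP site sequester the seed site in a
    hairpin.
    """
    fams: List[SeedFamily] = []
    used_sites: Set[str] = set()
    avoid = [p for _, p in cfg.rbp_motifs]
    motif_pattern = cfg.rbp_motifs[0][1] if cfg.rbp_motifs else None
    for i in range(cfg.n_families):
        fid = f"fam{i:02d}"
        site8 = None
        if i < cfg.n_planted and cfg.seed_complementarity and motif_pattern:
            site8 = _design_complementary_site(motif_pattern, rng, used_sites, avoid)
        for _ in range(500):
            if site8 is None:
                site8 = "".join(_BASES[rng.integers(0, 4, size=8)])
                if _overlaps_motif(site8, avoid):
                    site8 = None
                    continue
            m8_pattern = site8[:7]
            if m8_pattern not in used_sites:
                break
            site8 = None
        used_sites.add(m8_pattern)
        # mature positions 2-8 are the reverse complement of the m8 site
        core = reverse_complement(m8_pattern)
        tail = "".join(_BASES[rng.integers(0, 4, size=14)])
        mature = _BASES[rng.integers(0, 4)] + core + tail
        fams.append(SeedFamily.from_mature(fid, mature))
    return fams


def _proximal_slots(
    draft: UtrDraft, rbp_sites: Sequence[Tuple[int, int]], site_len: int
) -> List[int]:
    """Starts placing a site at gap <= 44 nt from some RBP instance."""
    slots: Set[int] = set()
    L = draft.length
    for a, b in rbp_sites:
        for gap in range(0, 45):
            for s in (b + gap, a - gap - site_len):
                if _free_slot(draft.occupied, s, site_len, L):
                    slots.add(s)
    return sorted(slots)


def plant_pairs_halflives_expression(
    cfg: SimConfig,
    drafts: Sequence[UtrDraft],
    families: Optional[List[SeedFamily]] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, uio.HalfLifeTable, Dict[str, int], List[SeedFamily], float]:
    """Site plan, half-life table and expression counts.

    Planted interacting families place a fraction ``colocalization_excess x
    baseline`` of their sites at gap <= 50 from an RBP site instance (the
    baseline is the empirical chance-proximity rate of uniform placement);
    the remaining sites are uniform.  Half-lives are log-normal with the
    ``halflife_effect`` multiplier applied to transcripts receiving a
    planted proximal pair, and read counts follow a Zipf law with the
    planted families ranked most expressed.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    families = generate_families(cfg, rng) if families is None else families
    planted = {f.family_id for f in families[: cfg.n_planted]}

    # actual RBP site instances (planted and background) per draft
    rbp_sites: Dict[str, List[Tuple[int, int]]] = {}
    for draft in drafts:
        seq = _to_seq(draft.ref)
        hits: List[Tuple[int, int]] = []
        for name, pattern in cfg.rbp_motifs:
            motif = parse_motif_consensus(pattern, name)
            hits.extend((h.start, h.end) for h in scan_motif_sites(seq, motif))
        rbp_sites[draft.transcript_id] = hits

    # empirical baseline: chance that a uniform 7-nt placement is proximal
    n_prox = n_tot = 0
    for draft in drafts:
        L = draft.length
        starts = np.arange(0, max(1, L - 7))
        prox = np.zeros(len(starts), dtype=bool)
        for a, b in rbp_sites[draft.transcript_id]:
            prox |= (starts >= a - 57) & (starts <= b + 50)
        n_prox += int(prox.sum())
        n_tot += len(starts)
    baseline = n_prox / max(1, n_tot)
    target = min(0.9, cfg.colocalization_excess * baseline)

    rows = []
    int_proximal: Set[str] = set()
    for fam in families:
        is_planted = fam.family_id in planted
        for seed_type, site in (("m8", fam.m8_site), ("1a", fam.a1_site)):
            n_sites = cfg.mirna_sites_per_family
            if is_planted:
                # the analysis scans patterns, so background occurrences of
                # the site pattern dilute the planted excess; aim the
                # *total* proximal fraction (planted + background) at the
                # configured multiple of baseline
                background = sum(
                    len(scan_motif_sites(_to_seq(d.ref), site)) for d in drafts
                )
                total = background + n_sites
                want = target * total - baseline * background
                frac = min(0.95, max(0.0, want / n_sites))
                n_planned_prox = rng.binomial(n_sites, frac)
            else:
                n_planned_prox = 0
            for k in range(n_sites):
                placed = None
                proximal = False
                if k < n_planned_prox:
                    for _ in range(30):
                        draft = drafts[rng.integers(len(drafts))]
                        slots = _proximal_slots(
                            draft, rbp_sites[draft.transcript_id], len(site)
                        )
                        if slots:
                            placed = (draft, int(slots[rng.integers(len(slots))]))
                            proximal = True
                            break
                if placed is None:
                    for _ in range(30):
                        draft = drafts[rng.integers(len(drafts))]
                        start = _draw_position(draft, len(site), rng, None, tries=5)
                        if start is not None:
                            placed = (draft, start)
                            break
                if placed is None:
                    continue
                draft, start = placed
                draft.paste(start, site.pattern)
                rows.append(
                    {
                        "transcript_id": draft.transcript_id,
                        "start": start,
                        "end": start + len(site),
                        "name": fam.family_id,
                        "kind": seed_type,
                        "conserved": False,
                        "proximal": proximal,
                    }
                )
                if proximal and is_planted:
                    int_proximal.add(draft.transcript_id)
    plan = pd.DataFrame(
        rows,
        columns=["transcript_id", "start", "end", "name", "kind", "conserved", "proximal"],
    )

    # the decay effect acts on the sequence configuration, not on planting
    # bookkeeping: any transcript whose final sequence carries an RBP site
    # with a planted-family seed-match site within 50 nt decays faster
    # (background occurrences of the planted patterns count too)
    planted_fams = [f for f in families if f.family_id in planted]
    if planted_fams and cfg.halflife_effect != 1.0:
        for draft in drafts:
            if draft.transcript_id in int_proximal:
                continue
            seq = _to_seq(draft.ref)
            rbp_hits = []
            for name, pattern in cfg.rbp_motifs:
                motif = parse_motif_consensus(pattern, name)
                rbp_hits.extend((h.start, h.end) for h in scan_motif_sites(seq, motif))
            if not rbp_hits:
                continue
            found = False
            for fam in planted_fams:
                for site in (fam.m8_site, fam.a1_site):
                    for h in scan_motif_sites(seq, site):
                        for a, b in rbp_hits:
                            gap = max(0, h.start - b) if h.start >= a else max(0, a - h.end)
                            if gap <= 50:
                                found = True
                                break
                        if found:
                            break
                    if found:
                        break
                if found:
                    break
            if found:
                int_proximal.add(draft.transcript_id)

    halflife_vals = {}
    for draft in drafts:
        hl = float(np.exp(rng.normal(cfg.halflife_log_mean, cfg.halflife_log_sigma)))
        if draft.transcript_id in int_proximal:
            hl *= cfg.halflife_effect
        halflife_vals[draft.transcript_id] = hl
    halflife = uio.HalfLifeTable(halflife_vals, "half_life")

    ranks = np.arange(1, len(families) + 1)
    order = list(range(cfg.n_planted)) + list(
        cfg.n_planted + rng.permutation(len(families) - cfg.n_planted)
    )
    expression = {
        families[idx].family_id: int(round(1e5 * ranks[r] ** (-cfg.expression_skew)))
        for r, idx in enumerate(order)
    }
    return plan, halflife, expression, families, baseline


def apply_site_plan(
    drafts: Sequence[UtrDraft],
    rbp_truth: pd.DataFrame,
    tree: PhyloTree,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> List[AlignedUTR]:
    """Rebuild aligned rows from the (now fully planted) reference rows."""
    return _build_rows(drafts, rbp_truth, tree, cfg, rng)


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class Truth:
    """Exact ground truth of one generated dataset."""

    planted_families: List[str]
    sites: pd.DataFrame  # rbp + miRNA planted sites with flags
    int_proximal_tids: Set[str]
    baseline_proximal: float

    def to_frame(self) -> pd.DataFrame:
        extra = [
            {"transcript_id": t, "start": -1, "end": -1, "name": t,
             "kind": "int_proximal_transcript", "conserved": False, "proximal": True}
            for t in sorted(self.int_proximal_tids)
        ] + [
            {"transcript_id": "", "start": -1, "end": -1, "name": f,
             "kind": "planted_family", "conserved": False, "proximal": False}
            for f in self.planted_families
        ]
        return pd.concat([self.sites, pd.DataFrame(extra)], ignore_index=True)


def generate_dataset(cfg: SimConfig) -> Tuple[uio.Dataset, Truth]:
    """Full synthetic dataset plus exact ground truth, deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    tree = generate_phylogeny(cfg.n_species, cfg.seed, cfg.tree_scale)
    _, rbp_truth, drafts, tree = generate_utr_alignments(cfg, tree, rng, build_rows=False)
    plan, halflife, expression, families, baseline = plant_pairs_halflives_expression(
        cfg, drafts, rng=rng
    )
    utrs = apply_site_plan(drafts, rbp_truth, tree, cfg, rng)
    motifs = [parse_motif_consensus(p, n) for n, p in cfg.rbp_motifs]
    dataset = uio.Dataset(
        tree=tree,
        utrs=utrs,
        motifs=motifs,
        families=families,
        expression=expression,
        halflife=halflife,
    )
    truth_sites = pd.concat([rbp_truth, plan], ignore_index=True)
    truth = Truth(
        planted_families=[f.family_id for f in families[: cfg.n_planted]],
        sites=truth_sites,
        int_proximal_tids={
            t for t in plan.loc[
                plan["proximal"] & plan["name"].isin(
                    f.family_id for f in families[: cfg.n_planted]
                ),
                "transcript_id",
            ]
        },
        baseline_proximal=baseline,
    )
    return dataset, truth


def write_dataset(
    dataset: uio.Dataset, directory: str, truth: Optional[Truth] = None
) -> None:
    """Write a dataset directory in the exact formats ``load_dataset`` reads."""
    os.makedirs(directory, exist_ok=True)
    p = {k: os.path.join(directory, v) for k, v in uio.DATASET_FILES.items()}
    uio.write_tree(dataset.tree, p["tree"])
    uio.write_maf(dataset.utrs, p["alignments"])
    uio.write_motifs(dataset.motifs, p["motifs"])
    uio.write_families(dataset.families, p["families"])
    uio.write_expression(dataset.expression, p["expression"])
    if dataset.halflife is not None:
        uio.write_halflife(dataset.halflife, p["halflife"])
    if dataset.regions is not None:
        uio.write_bed_regions(dataset.regions, p["regions"])
    if truth is not None:
        truth.to_frame().to_csv(
            os.path.join(directory, "truth.tsv"), sep="\t", index=False
        )
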