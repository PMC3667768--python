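"""Standard-format readers and writers.

Alignments travel as MAF (reference row first, s-lines only), phylogenies as
newick with branch lengths, sites/regions as BED6 (the score column carries
BLS x 1000 when present), plain sequences as FASTA, and the tabular inputs
(half-lives or decay rates, miRNA read counts, miRNA families, motif
definitions) as tab-separated text with a one-line header.

``load_dataset`` assembles the full cross-referenced object graph from a
directory laid out the way :mod:`utrcoop.simulate` writes it.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AlignedUTR,
    MotifConsensus,
    PhyloTree,
    SeedFamily,
    SiteCall,
    collapse_families,
    parse_motif_consensus,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# newick


def read_tree(path: str, ref_species: Optional[str] = None) -> PhyloTree:
    try:
        with open(path) as fh:
            return PhyloTree.from_newick(fh.read(), ref_species=ref_species)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"{path}: failed to parse newick tree: {exc}") from exc


def write_tree(tree: PhyloTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_newick() + "\n")


# ---------------------------------------------------------------------------
# MAF


def write_maf(utrs: Sequence[AlignedUTR], path: str) -> None:
    """One MAF block per UTR; the reference row comes first, src is
    ``species.transcript_id``."""
    blocks = []
    for u in utrs:
        recs = []
        order = [u.ref_species] + [s for s in u.rows if s != u.ref_species]
        for sp in order:
            row = u.rows[sp]
            size = len(row) - row.count("-")
            recs.append(
                SeqRecord(
                    Seq(row),
                    id=f"{sp}.{u.transcript_id}",
                    annotations={
                        "start": 0,
                        "size": size,
                        "strand": "+",
                        "srcSize": size,
                    },
                )
            )
        blocks.append(MultipleSeqAlignment(recs))
    with open(path, "w") as fh:
        AlignIO.write(blocks, fh, "maf")


def read_maf(path: str, min_ref_len: int = 10) -> Tuple[List[AlignedUTR], int]:
    """Read UTR alignment blocks; returns (utrs, n_dropped_short).

    Blocks whose ungapped reference row is shorter than ``min_ref_len`` are
    dropped with a logged count.
    """
    utrs: List[AlignedUTR] = []
    dropped = 0
    try:
        parsed = list(AlignIO.parse(path, "maf"))
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"{path}: failed to parse MAF: {exc}") from exc
    for i, block in enumerate(parsed):
        rows: Dict[str, str] = {}
        ref_species = None
        tid = None
        for rec in block:
            if "." not in rec.id:
                raise ValueError(
                    f"{path}: block {i}: src {rec.id!r} is not species.transcript"
                )
            sp, rec_tid = rec.id.split(".", 1)
            if ref_species is None:
                ref_species, tid = sp, rec_tid
            elif rec_tid != tid:
                raise ValueError(
                    f"{path}: block {i}: mixed transcript ids {tid!r} vs {rec_tid!r}"
                )
            rows[sp] = str(rec.seq).upper().replace("T", "U")
        lengths = {len(r) for r in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"{path}: block {i} ({tid}): row length mismatch")
        ref_len = len(rows[ref_species].replace("-", ""))
        if ref_len < min_ref_len:
            dropped += 1
            continue
        utrs.append(AlignedUTR(transcript_id=tid, ref_species=ref_species, rows=rows))
    if dropped:
        log.info("%s: dropped %d UTR blocks shorter than %d nt", path, dropped, min_ref_len)
    return utrs, dropped


# ---------------------------------------------------------------------------
# BED6


def write_bed_sites(sites: Iterable[SiteCall], path: str) -> None:
    with open(path, "w") as fh:
        for s in sites:
            score = "." if s.bls is None else str(int(round(s.bls * 1000)))
            fh.write(f"{s.transcript_id}\t{s.start}\t{s.end}\t{s.motif_name}\t{score}\t+\n")


def read_bed_sites(path: str) -> List[SiteCall]:
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            bls = None
            if len(f) >= 5 and f[4] not in (".", ""):
                bls = int(f[4]) / 1000.0
            sites.append(SiteCall(f[0], f[3], start, end, bls=bls))
    return sites


def write_bed_regions(regions: Mapping[str, Sequence[Tuple[int, int]]], path: str) -> None:
    with open(path, "w") as fh:
        for tid in regions:
            for j, (a, b) in enumerate(regions[tid]):
                fh.write(f"{tid}\t{a}\t{b}\tregion{j}\t.\t+\n")


def read_bed_regions(path: str) -> Dict[str, List[Tuple[int, int]]]:
    out: Dict[str, List[Tuple[int, int]]] = {}
    for s in read_bed_sites(path):
        out.setdefault(s.transcript_id, []).append((s.start, s.end))
    return out


# ---------------------------------------------------------------------------
# tabular text


def read_motifs(path: str) -> List[MotifConsensus]:
    """Two-column text: name, IUPAC pattern (header optional, '#' comments)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            f = line.split()
            if len(f) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name pattern'")
            try:
                out.append(parse_motif_consensus(f[1], name=f[0], kind="rbp"))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_motifs(motifs: Iterable[MotifConsensus], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("name\tpattern\n")
        for m in motifs:
            fh.write(f"{m.name}\t{m.pattern}\n")


def _read_tsv(path: str, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"{path}: failed to parse TSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_families(
    path: str, collapse: bool = True, orientation: str = "reverse_complement"
) -> List[SeedFamily]:
    """TargetScan-style family table: columns family_id, mature_seq."""
    df = _read_tsv(path, ["family_id", "mature_seq"])
    fams = []
    for row in df.itertuples(index=False):
        try:
            fams.append(
                SeedFamily.from_mature(str(row.family_id), str(row.mature_seq), orientation)
            )
        except ValueError as exc:
            raise ValueError(f"{path}: family {row.family_id}: {exc}") from exc
    return collapse_families(fams) if collapse else fams


def write_families(families: Iterable[SeedFamily], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tmature_seq\n")
        for f in families:
            fh.write(f"{f.family_id}\t{f.mature_seq}\n")


def read_expression(path: str) -> Dict[str, int]:
    df = _read_tsv(path, ["family_id", "reads"])
    counts = {str(r.family_id): int(r.reads) for r in df.itertuples(index=False)}
    if any(v < 0 for v in counts.values()):
        raise ValueError(f"{path}: negative read count")
    return counts


def write_expression(counts: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\treads\n")
        for k, v in counts.items():
            fh.write(f"{k}\t{v}\n")


@dataclass
class HalfLifeTable:
    """Per-transcript half-lives (hours) or decay rates (1/h).

    ``kind`` records which, so group comparisons can be direction-aware
    (shorter half-life == larger decay rate).
    """

    values: Dict[str, float]
    kind: str = "half_life"  # or "decay_rate"

    def __post_init__(self) -> None:
        if self.kind not in ("half_life", "decay_rate"):
            raise ValueError(f"unknown half-life table kind {self.kind!r}")
        bad = [t for t, v in self.values.items() if v <= 0]
        if bad:
            raise ValueError(f"non-positive values for {bad[:3]}")

    @property
    def faster_decay_is_smaller(self) -> bool:
        return self.kind == "half_life"


def read_halflife(path: str) -> HalfLifeTable:
    df = pd.read_csv(path, sep="\t")
    if "transcript_id" not in df.columns:
        raise ValueError(f"{path}: missing column 'transcript_id'")
    if "half_life_h" in df.columns:
        col, kind = "half_life_h", "half_life"
    elif "decay_rate_per_h" in df.columns:
        col, kind = "decay_rate_per_h", "decay_rate"
    else:
        raise ValueError(f"{path}: need a 'half_life_h' or 'decay_rate_per_h' column")
    vals = {str(r.transcript_id): float(getattr(r, col)) for r in df.itertuples(index=False)}
    return HalfLifeTable(vals, kind)


def write_halflife(table: HalfLifeTable, path: str) -> None:
    col = "half_life_h" if table.kind == "half_life" else "decay_rate_per_h"
    with open(path, "w") as fh:
        fh.write(f"transcript_id\t{col}\n")
        for k, v in table.values.items():
            fh.write(f"{k}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(seqs: Mapping[str, str], path: str) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()),
        path,
        "fasta",
    )


def read_fasta(path: str) -> Dict[str, str]:
    return {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(path, "fasta")
    }


# ---------------------------------------------------------------------------
# dataset bundle


#: conventional file names inside a dataset directory
DATASET_FILES = {
    "tree": "tree.nwk",
    "alignments": "alignments.maf",
    "motifs": "motifs.txt",
    "families": "families.tsv",
    "expression": "expression.tsv",
    "halflife": "halflives.tsv",
    "regions": "regions.bed",
}


@dataclass
class Dataset:
    """Cross-referenced inputs for one pipeline run."""

    tree: PhyloTree
    utrs: List[AlignedUTR]
    motifs: List[MotifConsensus]
    families: List[SeedFamily]
    expression: Dict[str, int] = field(default_factory=dict)
    halflife: Optional[HalfLifeTable] = None
    regions: Optional[Dict[str, List[Tuple[int, int]]]] = None
    n_dropped_short: int = 0

    def utr_by_id(self) -> Dict[str, AlignedUTR]:
        return {u.transcript_id: u for u in self.utrs}


def load_dataset(
    directory: str,
    paths: Optional[Mapping[str, str]] = None,
    orientation: str = "reverse_complement",
) -> Dataset:
    """Load a dataset directory into a :class:`Dataset`.

    ``paths`` overrides individual :data:`DATASET_FILES` entries.  UTRs
    shorter than 10 nt are dropped (with a logged count); species present in
    the alignments must exist in the tree.
    """
    p = {k: os.path.join(directory, v) for k, v in DATASET_FILES.items()}
    if paths:
        p.update(paths)
    tree = read_tree(p["tree"])
    utrs, dropped = read_maf(p["alignments"])
    motifs = read_motifs(p["motifs"])
    families = read_families(p["families"], orientation=orientation)
    expression = read_expression(p["expression"]) if os.path.exists(p["expression"]) else {}
    halflife = read_halflife(p["halflife"]) if os.path.exists(p["halflife"]) else None
    regions = read_bed_regions(p["regions"]) if os.path.exists(p["regions"]) else None
    tree_sp = set(tree.leaves)
    for u in utrs:
        extra = set(u.species) - tree_sp
        if extra:
            raise ValueError(
                f"{p['alignments']}: {u.transcript_id}: species {sorted(extra)} "
                "absent from tree"
            )
    return Dataset(
        tree=tree,
        utrs=utrs,
        motifs=motifs,
        families=families,
        expression=expression,
        halflife=halflife,
        regions=regions,
        n_dropped_short=dropped,
    )
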