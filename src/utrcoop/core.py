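"""Core domain types and sequence primitives.

Everything downstream works on three kinds of objects defined here:

* :class:`MotifConsensus` -- an IUPAC degenerate consensus for an RBP
  recognition element (e.g. PUM ``UGUANAUA``) or a miRNA seed-match site,
* :class:`AlignedUTR` -- one reference 3'UTR together with its gapped
  multi-species alignment rows and a reference-position <-> column map,
* :class:`SiteCall` -- a motif occurrence on the reference UTR, optionally
  annotated with a branch length score (BLS).

Coordinates are 0-based half-open on the reference UTR, 5'->3' sense.
Subject ``N`` bases never match any motif letter, including a pattern ``N``:
masked sequence must not create sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

RNA_BASES = "ACGU"

#: IUPAC degenerate nucleotide alphabet (RNA), letter -> set of concrete bases.
IUPAC: Dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA sequence (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    """Plain (non-reversed) complement of an RNA sequence."""
    return seq.translate(_COMPLEMENT)


@dataclass(frozen=True)
class MotifConsensus:
    """An IUPAC consensus pattern with a name and a kind.

    kind is one of ``rbp``, ``mirna_m8``, ``mirna_1a``.
    """

    name: str
    pattern: str
    kind: str = "rbp"

    def __len__(self) -> int:
        return len(self.pattern)

    def column_sets(self) -> List[frozenset]:
        """Per-position sets of concrete bases the pattern admits."""
        return [IUPAC[c] for c in self.pattern]

    def regex(self) -> "re.Pattern[str]":
        # character classes list concrete bases only, so a subject N can
        # never satisfy any position
        parts = []
        for c in self.pattern:
            bases = sorted(IUPAC[c])
            parts.append(bases[0] if len(bases) == 1 else "[%s]" % "".join(bases))
        return re.compile("".join(parts))

    def reversed(self) -> "MotifConsensus":
        """Letter-order reversal, degenerate letters preserved."""
        return replace(self, pattern=self.pattern[::-1])


def parse_motif_consensus(pattern: str, name: str, kind: str = "rbp") -> MotifConsensus:
    """Validate an IUPAC consensus; DNA ``T`` is accepted and mapped to ``U``.

    Raises ``ValueError`` naming the first offending character for anything
    outside the IUPAC alphabet, and for patterns shorter than 4 letters.
    """
    if kind not in ("rbp", "mirna_m8", "mirna_1a"):
        raise ValueError(f"unknown motif kind {kind!r}")
    if not pattern:
        raise ValueError("empty motif pattern")
    up = pattern.upper().replace("T", "U")
    for c in up:
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC character {c!r} in motif {name!r}")
    if len(up) < 4:
        raise ValueError(f"motif {name!r} shorter than 4 nt")
    return MotifConsensus(name=name, pattern=up, kind=kind)


@dataclass(frozen=True)
class SiteCall:
    """One motif occurrence on the reference UTR, [start, end) half-open."""

    transcript_id: str
    motif_name: str
    start: int
    end: int
    bls: Optional[float] = None

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)

    def with_bls(self, bls: float) -> "SiteCall":
        return replace(self, bls=bls)


def scan_motif_sites(
    seq: str, motif: MotifConsensus, transcript_id: str = ""
) -> List[SiteCall]:
    """All (possibly overlapping) motif occurrences in ``seq``, sorted by start.

    The subject must be over {A,C,G,U,N}; N matches nothing.
    """
    pat = re.compile("(?=(%s))" % motif.regex().pattern)
    L = len(motif)
    return [
        SiteCall(transcript_id, motif.name, m.start(), m.start() + L)
        for m in pat.finditer(seq)
    ]


def derive_seed_site_motifs(
    mature_seq: str, family_id: str = "", orientation: str = "reverse_complement"
) -> Tuple[MotifConsensus, MotifConsensus]:
    """Seed-match site consensi for a mature miRNA.

    m8 site = reverse complement of miRNA nucleotides 2-8 (7 nt); 1A site =
    reverse complement of nucleotides 2-7 followed by an A (7 nt).  The
    ``orientation`` switch selects ``complement`` to take the plain
    (non-reversed) complement instead.
    """
    seq = mature_seq.upper().replace("T", "U")
    if len(seq) < 8:
        raise ValueError(
            f"mature miRNA {family_id or seq!r} shorter than 8 nt ({len(seq)})"
        )
    if orientation == "reverse_complement":
        m8 = reverse_complement(seq[1:8])
        a1 = reverse_complement(seq[1:7]) + "A"
    elif orientation == "complement":
        m8 = complement(seq[1:8])
        a1 = complement(seq[1:7]) + "A"
    else:
        raise ValueError(f"unknown seed orientation {orientation!r}")
    return (
        MotifConsensus(name=f"{family_id}|m8", pattern=m8, kind="mirna_m8"),
        MotifConsensus(name=f"{family_id}|1a", pattern=a1, kind="mirna_1a"),
    )


@dataclass
class SeedFamily:
    """A miRNA family: mature sequence plus its two derived seed-match sites."""

    family_id: str
    mature_seq: str
    m8_site: MotifConsensus
    a1_site: MotifConsensus
    expressed: bool = False
    members: Tuple[str, ...] = ()

    @classmethod
    def from_mature(
        cls, family_id: str, mature_seq: str, orientation: str = "reverse_complement"
    ) -> "SeedFamily":
        m8, a1 = derive_seed_site_motifs(mature_seq, family_id, orientation)
        return cls(family_id, mature_seq.upper().replace("T", "U"), m8, a1)

    def seed_au_count(self) -> int:
        """Number of A/U bases among the 7 seed-match positions (m8 site)."""
        return sum(1 for c in self.m8_site.pattern if c in "AU")


def collapse_families(families: Sequence[SeedFamily]) -> List[SeedFamily]:
    """Merge families with identical m8 site patterns into one.

    The merged id concatenates member ids with ``/`` (mirroring conventions
    like miR-221/222); the first member's mature sequence is kept.
    """
    by_site: Dict[str, List[SeedFamily]] = {}
    order: List[str] = []
    for f in families:
        key = f.m8_site.pattern
        if key not in by_site:
            order.append(key)
        by_site.setdefault(key, []).append(f)
    out = []
    for key in order:
        group = by_site[key]
        if len(group) == 1:
            out.append(group[0])
            continue
        fid = "/".join(f.family_id for f in group)
        merged = SeedFamily.from_mature(fid, group[0].mature_seq)
        merged.members = tuple(f.family_id for f in group)
        merged.expressed = any(f.expressed for f in group)
        out.append(merged)
    return out


def compute_au_fraction(seq: str) -> float:
    """(#A + #U) / (#A + #C + #G + #U); N is excluded from the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    denom = sum(seq.count(b) for b in RNA_BASES)
    if denom == 0:
        raise ValueError("AU fraction undefined: no unambiguous bases")
    return (seq.count("A") + seq.count("U")) / denom


def restrict_sites_to_regions(
    sites: Iterable[SiteCall],
    regions: Mapping[str, Sequence[Tuple[int, int]]],
) -> List[SiteCall]:
    """Keep sites fully contained in some region of their transcript.

    ``regions`` maps transcript id to [start, end) intervals (Par-CLIP style
    binding-region restriction).
    """
    kept = []
    for s in sites:
        for a, b in regions.get(s.transcript_id, ()):
            if a <= s.start and s.end <= b:
                kept.append(s)
                break
    return kept


# ---------------------------------------------------------------------------
# Aligned UTRs


@dataclass
class AlignedUTR:
    """A reference 3'UTR with its gapped multi-species alignment rows.

    ``rows`` maps species name to the gapped row; the reference row ungapped
    reproduces ``ref_seq``.  ``ref_to_column[i]`` is the alignment column of
    reference position ``i``.
    """

    transcript_id: str
    ref_species: str
    rows: Dict[str, str]
    ref_seq: str = field(init=False)
    ref_to_column: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.ref_species not in self.rows:
            raise ValueError(
                f"{self.transcript_id}: reference species {self.ref_species!r} "
                "missing from alignment rows"
            )
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.transcript_id}: alignment rows differ in length")
        ref_row = self.rows[self.ref_species]
        self.ref_seq = ref_row.replace("-", "")
        if len(self.ref_seq) < 10:
            raise ValueError(
                f"{self.transcript_id}: reference UTR shorter than 10 nt"
            )
        self.ref_to_column = np.array(
            [i for i, c in enumerate(ref_row) if c != "-"], dtype=np.int64
        )

    @property
    def species(self) -> List[str]:
        return list(self.rows)

    @property
    def ref_length(self) -> int:
        return len(self.ref_seq)

    def ungapped(self, sp: str) -> str:
        return self.rows[sp].replace("-", "")

    def row_positions(self, sp: str) -> np.ndarray:
        """Alignment column of each ungapped position of species ``sp``."""
        return np.array(
            [i for i, c in enumerate(self.rows[sp]) if c != "-"], dtype=np.int64
        )

    def column_to_ref(self) -> np.ndarray:
        """For each alignment column, the nearest reference position at or
        left of it (-1 before the first reference base)."""
        ncol = len(self.rows[self.ref_species])
        out = np.full(ncol, -1, dtype=np.int64)
        out[self.ref_to_column] = np.arange(len(self.ref_to_column))
        return np.maximum.accumulate(out)


# ---------------------------------------------------------------------------
# Phylogeny


class PhyloTree:
    """A rooted phylogeny with branch lengths, wrapping a dendropy tree.

    The reference species must be a leaf; ``total_length`` is the sum of all
    edge lengths (substitutions/site) over which a branch length score is a
    fraction.
    """

    def __init__(self, tree: dendropy.Tree, ref_species: Optional[str] = None):
        self._tree = tree
        names = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names in tree")
        self.leaves = names
        self.ref_species = ref_species if ref_species is not None else names[0]
        if self.ref_species not in names:
            raise ValueError(f"reference species {self.ref_species!r} not a leaf")
        self.total_length = sum(
            e.length or 0.0 for e in tree.preorder_edge_iter() if e.head_node.parent_node
        )
        if self.total_length <= 0:
            raise ValueError("tree has non-positive total branch length")
        pdm = tree.phylogenetic_distance_matrix()
        self._dist: Dict[Tuple[str, str], float] = {}
        for t1 in tree.taxon_namespace:
            for t2 in tree.taxon_namespace:
                self._dist[(t1.label, t2.label)] = pdm.patristic_distance(t1, t2)

    @classmethod
    def from_newick(cls, text: str, ref_species: Optional[str] = None) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(data=text, schema="newick")
        except Exception as exc:  # dendropy raises its own hierarchy
            raise ValueError(f"invalid newick tree: {exc}") from exc
        return cls(tree, ref_species)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    def distance(self, a: str, b: str) -> float:
        """Patristic (path-length) distance between two leaves."""
        return self._dist[(a, b)]

    def spanning_length(self, species: Iterable[str]) -> float:
        """Total branch length of the minimal subtree connecting ``species``.

        An edge belongs to the spanning subtree iff the leaf set on its head
        side and the leaf set on its tail side both contain members.
        """
        members = set(species)
        unknown = members - set(self.leaves)
        if unknown:
            raise ValueError(f"species not in tree: {sorted(unknown)}")
        if len(members) <= 1:
            return 0.0
        total = 0.0
        for node in self._tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            below = {lf.taxon.label for lf in node.leaf_iter()}
            inside = len(members & below)
            if 0 < inside < len(members):
                total += node.edge.length or 0.0
        return total

    def restrict(self, species: Iterable[str]) -> "PhyloTree":
        """Subtree induced by a species subset (e.g. a primate-only variant)."""
        keep = set(species)
        sub = self._tree.extract_tree_with_taxa_labels(keep)
        ref = self.ref_species if self.ref_species in keep else None
        return PhyloTree(sub, ref)
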