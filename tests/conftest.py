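"""Shared fixtures: tiny hand-built trees/alignments and cached synthetic runs."""

from __future__ import annotations

import numpy as np
import pytest

from utrcoop.core import AlignedUTR, PhyloTree, parse_motif_consensus


@pytest.fixture(scope="session")
def balanced_tree() -> PhyloTree:
    """((Ref:1,S1:1):1,(S2:1,S3:1):1); total length 6."""
    return PhyloTree.from_newick("((Ref:1,S1:1):1,(S2:1,S3:1):1);", ref_species="Ref")


@pytest.fixture
def pum_motif():
    return parse_motif_consensus("UGUANAUA", "PUM")


def make_block(rows: dict, ref: str = "Ref", tid: str = "tx0") -> AlignedUTR:
    return AlignedUTR(transcript_id=tid, ref_species=ref, rows=rows)


@pytest.fixture
def block_factory():
    return make_block


def random_rna(rng: np.random.Generator, n: int, p_n: float = 0.0) -> str:
    bases = np.array(list("ACGUN"))
    probs = np.array([(1 - p_n) / 4] * 4 + [p_n])
    return "".join(rng.choice(bases, size=n, p=probs))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
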