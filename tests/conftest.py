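"""Shared fixtures: small simulated datasets and transformation helpers."""

from __future__ import annotations

import copy

import numpy as np
import pytest

from leadscan.geometry import ContigInput
from leadscan.io_formats import HomologyHit
from leadscan.synthetic_data import SimConfig, SimulatedDataset, simulate_contigs


@pytest.fixture(scope="session")
def small_dataset() -> SimulatedDataset:
    """50 contigs with planted enrichment, duplicates and islands (no sequences)."""
    cfg = SimConfig(
        seed=4202,
        n_contigs=50,
        genes_per_contig=(30, 50),
        dup_groups=5,
        dup_copies=3,
        island_prob=0.4,
        emit_sequences=False,
    )
    return simulate_contigs(cfg)


@pytest.fixture(scope="session")
def sequence_dataset() -> SimulatedDataset:
    """A small fixture with contig sequences and planted Frpo elements."""
    cfg = SimConfig(
        seed=907,
        n_contigs=6,
        genes_per_contig=(12, 18),
        frpo_per_contig=1,
        emit_sequences=True,
    )
    return simulate_contigs(cfg)


def mirror_contig_input(ci: ContigInput, length: int | None = None) -> ContigInput:
    """Apply x -> L - x and strand flips to a whole contig bundle."""
    if length is None:
        length = max(max(g.end for g in ci.genes), max((h.send for h in ci.orit_hits), default=0)) + 137
    out = copy.deepcopy(ci)
    for g in out.genes:
        g.start, g.end = length - g.end, length - g.start
        g.strand = "+" if g.strand == "-" else "-"
    out.orit_hits = [
        HomologyHit(
            query_id=h.query_id,
            subject_id=h.subject_id,
            sstart=length - h.send,
            send=length - h.sstart,
            strand="+" if h.strand == "-" else "-",
            percent_identity=h.percent_identity,
            bit_score=h.bit_score,
            e_value=h.e_value,
        )
        for h in out.orit_hits
    ]
    if out.sequence is not None:
        from leadscan._seq import revcomp

        pad = length - len(out.sequence)
        out.sequence = revcomp(out.sequence) if pad == 0 else revcomp(out.sequence + "A" * pad)
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
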