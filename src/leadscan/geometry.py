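"""Orient contigs around the oriT: leading/lagging ORF indices and T-strand flags.

The leading region is the side of the oriT opposite the relaxase (the
relaxase travels last during conjugation).  ORF indices are assigned
outward from the oriT midpoint: 0, 1, 2, ... on the leading side and
-1, -2, ... on the lagging side, matching the convention in which
position 0 is the first ORF of the leading region.

A gene is *T-strand expressible* when it can be transcribed from the
transferred single strand before second-strand synthesis.  Under the
default ``toward_oriT`` convention this means the gene's transcription
direction opposes the leading direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._seq import contains, interval_gap
from .io_formats import GeneRecord, HomologyHit

log = logging.getLogger(__name__)

DEFAULT_MAX_DISTANCE = 3500

REJECTION_REASONS = (
    "too_many_relaxases",
    "too_far",
    "orit_inside_relaxase",
    "edge_placement",
    "no_orit",
    "no_relaxase",
)


class DegenerateGeometryError(ValueError):
    """Relaxase and oriT midpoints coincide; leading side undefined."""


@dataclass(slots=True)
class OriTAssignment:
    """The oriT anchor of a contig and its relaxase partner."""

    contig_id: str
    orit_start: int
    orit_end: int
    orit_hit: HomologyHit
    relaxase_gene_id: str
    relaxase_start: int
    relaxase_end: int

    @property
    def distance_bp(self) -> int:
        """Nucleotides between the relaxase gene and the oriT (0 if overlapping)."""
        return interval_gap(self.relaxase_start, self.relaxase_end, self.orit_start, self.orit_end)

    @property
    def orit_midpoint(self) -> float:
        return (self.orit_start + self.orit_end) / 2.0

    @property
    def relaxase_midpoint(self) -> float:
        return (self.relaxase_start + self.relaxase_end) / 2.0


@dataclass(slots=True)
class ContigGeometry:
    """Per-contig oriented coordinate system."""

    contig_id: str
    leading_direction: int  # +1: leading positions grow with contig coordinate
    relative_position: dict[str, int]
    t_strand_expressible: dict[str, bool]
    orit: OriTAssignment | None = None

    def leading_genes(self, max_position: int | None = None) -> list[str]:
        out = [g for g, p in self.relative_position.items() if p >= 0]
        if max_position is not None:
            out = [g for g in out if self.relative_position[g] <= max_position]
        return sorted(out, key=lambda g: self.relative_position[g])


def select_best_orit(hits: Sequence[HomologyHit]) -> HomologyHit | None:
    """Best-scoring oriT hit; ties by lowest e-value, leftmost start, query id."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.bit_score, h.e_value, h.sstart, h.query_id))


@dataclass(slots=True)
class ContigInput:
    """Everything geometry needs to know about one contig."""

    contig_id: str
    genes: list[GeneRecord]
    relaxase_gene_ids: list[str]
    orit_hits: list[HomologyHit]
    mob_type: str | None = None
    sequence: str | None = None


def _resolve_orit(
    contig: ContigInput, max_distance: int
) -> tuple[OriTAssignment | None, str | None]:
    """Build the oriT/relaxase assignment for one contig or a rejection reason."""
    genes_by_id = {g.gene_id: g for g in contig.genes}
    relaxase_genes = [genes_by_id[g] for g in contig.relaxase_gene_ids if g in genes_by_id]
    if not relaxase_genes:
        return None, "no_relaxase"
    if len(relaxase_genes) > 2:
        return None, "too_many_relaxases"
    best = select_best_orit(contig.orit_hits)
    if best is None:
        return None, "no_orit"
    # anchor on the relaxase gene nearest the oriT
    relax = min(
        relaxase_genes,
        key=lambda g: (interval_gap(g.start, g.end, best.sstart, best.send), g.gene_id),
    )
    assignment = OriTAssignment(
        contig_id=contig.contig_id,
        orit_start=best.sstart,
        orit_end=best.send,
        orit_hit=best,
        relaxase_gene_id=relax.gene_id,
        relaxase_start=relax.start,
        relaxase_end=relax.end,
    )
    if assignment.distance_bp > max_distance:
        return None, "too_far"
    if contains(relax.start, relax.end, best.sstart, best.send):
        return None, "orit_inside_relaxase"
    return assignment, None


def qc_filter_contigs(
    contigs: Iterable[ContigInput],
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> tuple[list[tuple[ContigInput, OriTAssignment]], dict[str, str]]:
    """Apply the relaxase/oriT quality filters.

    Returns the passing (contig, assignment) pairs and a per-contig
    rejection reason for the rest.  Partial oriT-relaxase overlap is
    retained; full containment, edge placement, more than two relaxase
    hits and distances above ``max_distance`` are rejected.
    """
    passing: list[tuple[ContigInput, OriTAssignment]] = []
    rejected: dict[str, str] = {}
    for contig in contigs:
        assignment, reason = _resolve_orit(contig, max_distance)
        if reason is not None:
            rejected[contig.contig_id] = reason
            continue
        assert assignment is not None
        if _edge_placed(contig.genes, assignment):
            rejected[contig.contig_id] = "edge_placement"
            continue
        passing.append((contig, assignment))
    return passing, rejected


def _edge_placed(genes: Sequence[GeneRecord], assignment: OriTAssignment) -> bool:
    ordered = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
    if not ordered:
        return True
    first, last = ordered[0], ordered[-1]
    if assignment.relaxase_gene_id in (first.gene_id, last.gene_id):
        return True
    mid = assignment.orit_midpoint
    return not (first.midpoint < mid < last.midpoint)


def assign_relative_positions(
    genes: Sequence[GeneRecord],
    assignment: OriTAssignment,
    convention: str = "toward_oriT",
) -> ContigGeometry:
    """Index ORFs outward from the oriT and flag T-strand expressibility.

    Leading direction is the sign of (oriT midpoint - relaxase midpoint);
    a gene's side is decided by its midpoint (ties at the oriT midpoint go
    to the leading side, i.e. position 0).
    """
    om, rm = assignment.orit_midpoint, assignment.relaxase_midpoint
    if om == rm:
        raise DegenerateGeometryError(
            f"{assignment.contig_id}: oriT and relaxase midpoints coincide at {om}"
        )
    direction = 1 if om > rm else -1

    leading, lagging = [], []
    for g in genes:
        offset = (g.midpoint - om) * direction
        (leading if offset >= 0 else lagging).append((abs(offset), g))
    leading.sort(key=lambda t: (t[0], t[1].gene_id))
    lagging.sort(key=lambda t: (t[0], t[1].gene_id))

    rel: dict[str, int] = {}
    for idx, (_, g) in enumerate(leading):
        rel[g.gene_id] = idx
    for idx, (_, g) in enumerate(lagging):
        rel[g.gene_id] = -(idx + 1)

    flags = {
        g.gene_id: t_strand_expressible(g, direction, convention) for g in genes
    }
    return ContigGeometry(
        contig_id=assignment.contig_id,
        leading_direction=direction,
        relative_position=rel,
        t_strand_expressible=flags,
        orit=assignment,
    )


def t_strand_expressible(gene: GeneRecord, leading_direction: int, convention: str = "toward_oriT") -> bool:
    """Can the gene be transcribed from the transferred single strand?

    ``toward_oriT`` (default): the T-strand's 5' end is at the nic, so a gene
    is expressible iff its transcription direction opposes the leading
    direction.  ``away_from_oriT`` flips the convention.
    """
    strand_dir = 1 if gene.strand == "+" else -1
    if convention == "toward_oriT":
        return strand_dir == -leading_direction
    if convention == "away_from_oriT":
        return strand_dir == leading_direction
    raise ValueError(f"unknown T-strand convention: {convention}")


GEOMETRY_TABLE_COLUMNS = (
    "contig_id",
    "gene_id",
    "relative_position",
    "t_strand_expressible",
    "leading_direction",
)


def write_geometry_table(geometries: Sequence[ContigGeometry], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GEOMETRY_TABLE_COLUMNS) + "\n")
        for geo in geometries:
            for gid in sorted(geo.relative_position, key=lambda g: geo.relative_position[g]):
                fh.write(
                    f"{geo.contig_id}\t{gid}\t{geo.relative_position[gid]}\t"
                    f"{int(geo.t_strand_expressible[gid])}\t{geo.leading_direction}\n"
                )


def read_geometry_table(path) -> list[ContigGeometry]:
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    if not lines or tuple(lines[0].split("\t")) != GEOMETRY_TABLE_COLUMNS:
        raise ValueError(f"{path}: unexpected geometry table header")
    geos: dict[str, ContigGeometry] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        cid, gid, rel, t, ld = line.split("\t")
        geo = geos.setdefault(cid, ContigGeometry(cid, int(ld), {}, {}))
        geo.relative_position[gid] = int(rel)
        geo.t_strand_expressible[gid] = bool(int(t))
    return list(geos.values())
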