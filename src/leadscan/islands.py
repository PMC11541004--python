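"""Anti-defence island delineation in leading regions.

An island is a maximal run of island-qualifying genes (anti-defence genes
plus protective cargo: MTases, SSBs, toxin-antitoxin systems) that starts
within the first 28 leading positions.  Up to ``max_gap`` consecutive
non-qualifying genes are tolerated inside a run; a umu-like gene (plasmid
umuC/umuD homologue) terminates the island and is recorded as its far
boundary, mirroring the oriT ... umuCD architecture seen in real islands.
Runs with fewer than ``min_members`` qualifying genes are discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .geometry import ContigGeometry

DEFAULT_QUALIFYING = frozenset(
    {"anti_crispr", "anti_restriction", "sos_inhibitor", "mtase", "ssb", "toxin_antitoxin"}
)
DEFAULT_MAX_GAP = 2
DEFAULT_MIN_MEMBERS = 3
LEADING_START_MAX = 27


@dataclass(slots=True)
class Island:
    contig_id: str
    start_position: int  # relative position of first qualifying member
    end_position: int  # relative position of last qualifying member (inclusive)
    member_gene_ids: list[str]  # qualifying members, in positional order
    boundary_start: str = "oriT"
    boundary_end: str = "none"  # "umu_like_operon" or "none"
    composition: dict[str, int] = field(default_factory=dict)
    beyond_leading: list[str] = field(default_factory=list)  # members past position 27

    @property
    def n_members(self) -> int:
        return len(self.member_gene_ids)


def detect_islands(
    geometry: ContigGeometry,
    categories: Mapping[str, str],
    qualifying: frozenset[str] = DEFAULT_QUALIFYING,
    max_gap: int = DEFAULT_MAX_GAP,
    min_members: int = DEFAULT_MIN_MEMBERS,
    leading_start_max: int = LEADING_START_MAX,
) -> list[Island]:
    """Scan the leading side of one contig for islands.

    Walks positions 0, 1, 2, ... outward.  A run starts at a qualifying gene
    with position <= ``leading_start_max`` and may extend past it (members
    beyond are flagged, not dropped).  A umu-like gene closes the current
    run with boundary ``umu_like_operon``; more than ``max_gap`` consecutive
    other non-qualifying genes close it with boundary ``none``.
    """
    order = geometry.leading_genes()
    islands: list[Island] = []

    current: list[str] = []
    gap = 0
    boundary = "none"

    def flush(boundary_end: str) -> None:
        nonlocal current
        if len(current) >= min_members:
            positions = [geometry.relative_position[g] for g in current]
            islands.append(
                Island(
                    contig_id=geometry.contig_id,
                    start_position=min(positions),
                    end_position=max(positions),
                    member_gene_ids=list(current),
                    boundary_end=boundary_end,
                    composition=_composition(current, categories),
                    beyond_leading=[
                        g for g in current
                        if geometry.relative_position[g] > leading_start_max
                    ],
                )
            )
        current = []

    for gid in order:
        pos = geometry.relative_position[gid]
        cat = categories.get(gid, "uncharacterized")
        if cat == "umu_like":
            flush("umu_like_operon")
            gap = 0
            continue
        if cat in qualifying:
            if not current and pos > leading_start_max:
                continue  # runs must start within the leading window
            current.append(gid)
            gap = 0
        else:
            if current:
                gap += 1
                if gap > max_gap:
                    flush("none")
                    gap = 0
    flush("none")
    return islands


def _composition(gene_ids: Sequence[str], categories: Mapping[str, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for g in gene_ids:
        cat = categories.get(g, "uncharacterized")
        counts[cat] = counts.get(cat, 0) + 1
    return dict(sorted(counts.items()))


def summarize_island(
    island: Island,
    geometry: ContigGeometry,
    categories: Mapping[str, str],
    enriched_uncharacterized: frozenset[str] = frozenset(),
) -> dict:
    """Composition record for one island.

    ``enriched_uncharacterized`` may list gene ids belonging to
    uncharacterized-but-leading-enriched families, flagged separately.
    """
    flags = [geometry.t_strand_expressible[g] for g in island.member_gene_ids]
    return {
        "contig_id": island.contig_id,
        "span": [island.start_position, island.end_position],
        "n_members": island.n_members,
        "composition": island.composition,
        "fraction_t_strand": sum(flags) / len(flags) if flags else 0.0,
        "boundary_start": island.boundary_start,
        "boundary_end": island.boundary_end,
        "uncharacterized_enriched_members": sorted(
            g for g in island.member_gene_ids if g in enriched_uncharacterized
        ),
        "members_beyond_leading": island.beyond_leading,
    }


def write_islands(
    islands: Sequence[Island],
    geometries: Mapping[str, ContigGeometry],
    categories: Mapping[str, str],
    tsv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    with open(tsv_path, "w") as fh:
        fh.write(
            "contig_id\tstart_position\tend_position\tn_members\tboundary_end\t"
            "fraction_t_strand\tmembers\n"
        )
        for isl in islands:
            geo = geometries[isl.contig_id]
            flags = [geo.t_strand_expressible[g] for g in isl.member_gene_ids]
            frac = sum(flags) / len(flags) if flags else 0.0
            fh.write(
                f"{isl.contig_id}\t{isl.start_position}\t{isl.end_position}\t"
                f"{isl.n_members}\t{isl.boundary_end}\t{frac:.3f}\t"
                f"{','.join(isl.member_gene_ids)}\n"
            )
    if json_path is not None:
        records = [
            summarize_island(isl, geometries[isl.contig_id], categories) for isl in islands
        ]
        Path(json_path).write_text(json.dumps(records, indent=2) + "\n")
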