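"""End-to-end orchestration: ingest -> QC -> dedup -> geometry -> statistics.

``RunConfig`` carries every stage parameter with defaults matching the
standard analysis (e-value 1e-6, at most 2 relaxase hits, relaxase-oriT
distance <= 3,500 bp, dedup threshold 0.9, five-ORF window, >= 50 ORFs per
tested position, alpha 0.001, leading range 0-27, regulatory regions
50-350 bp, word size 5).  ``run_pipeline`` executes the stages in order and
writes the output bundle plus a manifest echoing every parameter; reruns
with the same config and inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from . import dedup as dedup_mod
from . import enrichment, frpo_scan, islands as islands_mod
from .geometry import (
    ContigGeometry,
    ContigInput,
    assign_relative_positions,
    qc_filter_contigs,
    write_geometry_table,
)
from .io_formats import (
    CategoryMap,
    GeneRecord,
    assign_categories,
    read_category_map,
    read_gene_annotations,
    read_homology_hits,
    write_gene_table,
)
from .orit_search import ScoringScheme, hits_as_homology, seed_and_extend

log = logging.getLogger(__name__)


class PipelineInputError(ValueError):
    """A required input file is missing or unreadable."""


@dataclass
class RunConfig:
    """Paths and stage parameters for a full run."""

    # inputs
    genes: str = ""
    fasta: str = ""
    relaxase_hits: str = ""
    function_hits: str = ""
    orit_hits: str = ""  # blast6; if empty, orit_queries is searched internally
    orit_queries: str = ""
    category_map: str = ""
    membership: str = ""
    mob_table: str = ""
    known_frpo: str = ""
    outdir: str = "leadscan_out"
    # stage parameters (defaults = the standard parameterization)
    e_value_threshold: float = 1e-6
    max_relaxase_hits: int = 2
    max_orit_distance: int = 3500
    dedup_threshold: float = 0.9
    window: int = 5
    min_orfs: int = 50
    alpha: float = 0.001
    leading_range: tuple[int, int] = (0, 27)
    family_min_size: int = 5
    region_len_min: int = 50
    region_len_max: int = 350
    word_size: int = 5
    min_raw_score: int = 20
    island_max_gap: int = 2
    island_min_members: int = 3
    t_strand_convention: str = "toward_oriT"
    mob_exclude: tuple[str, ...] = ()
    report_min_sequences: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("leading_range", "mob_exclude"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["leading_range"] = list(self.leading_range)
        d["mob_exclude"] = list(self.mob_exclude)
        return d


@dataclass
class PipelineResult:
    config: RunConfig
    geometries: dict[str, ContigGeometry]
    categories: dict[str, str]
    rejected: dict[str, str]
    dedup: dedup_mod.DedupResult | None
    positions: "object"  # pandas DataFrame
    families: "object"
    islands: list
    frpo_candidates: list
    outputs: dict[str, Path]


OUTPUT_FILES = {
    "gene_table": "genes_annotated.tsv",
    "qc_log": "qc_log.tsv",
    "dedup": "dedup.tsv",
    "geometry": "geometry.tsv",
    "positions": "positions.tsv",
    "families": "families.tsv",
    "islands": "islands.tsv",
    "islands_json": "islands.json",
    "frpo": "frpo.tsv",
    "manifest": "manifest.json",
}


def _read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _read_two_column(path: str | Path, header: tuple[str, str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if tuple(parts[:2]) == header:
            continue
        out[parts[0]] = parts[1]
    return out


def build_contig_inputs(
    genes: list[GeneRecord],
    relaxase_hits,
    orit_hits,
    mob: dict[str, str] | None = None,
    sequences: dict[str, str] | None = None,
) -> list[ContigInput]:
    by_contig: dict[str, ContigInput] = {}
    for g in genes:
        ci = by_contig.setdefault(
            g.contig_id, ContigInput(g.contig_id, [], [], [], None, None)
        )
        ci.genes.append(g)
    gene_contig = {g.gene_id: g.contig_id for g in genes}
    for h in relaxase_hits:
        cid = gene_contig.get(h.subject_id)
        if cid is not None:
            by_contig[cid].relaxase_gene_ids.append(h.subject_id)
    for h in orit_hits:
        if h.subject_id in by_contig:
            by_contig[h.subject_id].orit_hits.append(h)
    for ci in by_contig.values():
        ci.mob_type = (mob or {}).get(ci.contig_id)
        ci.sequence = (sequences or {}).get(ci.contig_id)
    return [by_contig[c] for c in sorted(by_contig)]


def run_pipeline(config: RunConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = {k: outdir / v for k, v in OUTPUT_FILES.items()}

    # ---- ingest -----------------------------------------------------------
    stage = "ingest"
    try:
        genes = read_gene_annotations(config.genes)
        cmap = read_category_map(config.category_map)
        relaxase_hits = read_homology_hits(
            config.relaxase_hits, "hmm_tblout", config.e_value_threshold
        )
        function_hits = (
            read_homology_hits(config.function_hits, "hmm_tblout", config.e_value_threshold)
            if config.function_hits
            else []
        )
        sequences = _read_fasta(config.fasta) if config.fasta else {}
        mob = (
            _read_two_column(config.mob_table, ("contig_id", "mob_type"))
            if config.mob_table
            else {}
        )
    except FileNotFoundError as exc:
        raise PipelineInputError(f"stage {stage}: {exc}") from exc

    assign_categories(genes, relaxase_hits + function_hits, cmap)
    categories = {g.gene_id: g.category for g in genes}
    write_gene_table(genes, outputs["gene_table"])

    # ---- oriT resolution --------------------------------------------------
    stage = "orit"
    if config.orit_hits:
        orit_hits = read_homology_hits(config.orit_hits, "blast6", config.e_value_threshold)
    elif config.orit_queries and sequences:
        queries = _read_fasta(config.orit_queries)
        scheme = ScoringScheme(word_size=config.word_size, min_raw_score=config.min_raw_score)
        found = []
        for cid in sorted(sequences):
            for qid in sorted(queries):
                found.extend(
                    seed_and_extend(queries[qid], sequences[cid], scheme, qid, cid)
                )
        orit_hits = hits_as_homology(found)
    else:
        raise PipelineInputError("stage orit: need either orit_hits or orit_queries + fasta")

    contigs = build_contig_inputs(genes, relaxase_hits, orit_hits, mob, sequences)

    # ---- QC ---------------------------------------------------------------
    passing, rejected = qc_filter_contigs(contigs, config.max_orit_distance)
    with open(outputs["qc_log"], "w") as fh:
        fh.write("contig_id\tstatus\treason\n")
        for ci, _ in passing:
            fh.write(f"{ci.contig_id}\tpass\t.\n")
        for cid in sorted(rejected):
            fh.write(f"{cid}\tfail\t{rejected[cid]}\n")

    # ---- dedup ------------------------------------------------------------
    stage = "dedup"
    dedup_result = None
    if config.membership:
        membership = dedup_mod.read_membership(config.membership)
        contig_table = {
            ci.contig_id: [g.gene_id for g in ci.genes] for ci, _ in passing
        }
        dedup_result = dedup_mod.deduplicate(contig_table, membership, config.dedup_threshold)
        dedup_mod.write_dedup_table(dedup_result, outputs["dedup"])
        keep = set(dedup_result.representatives)
        passing = [(ci, a) for ci, a in passing if ci.contig_id in keep]
    else:
        membership = {}

    # ---- geometry ---------------------------------------------------------
    stage = "geometry"
    geometries: dict[str, ContigGeometry] = {}
    for ci, assignment in passing:
        geometries[ci.contig_id] = assign_relative_positions(
            ci.genes, assignment, config.t_strand_convention
        )
    write_geometry_table([geometries[c] for c in sorted(geometries)], outputs["geometry"])

    # ---- enrichment -------------------------------------------------------
    stage = "enrichment"
    mob_of = {ci.contig_id: (ci.mob_type or "NA") for ci, _ in passing}
    analysed = [
        geometries[c] for c in sorted(geometries) if mob_of.get(c) not in config.mob_exclude
    ]
    table = enrichment.tally_positions(analysed, categories)
    positions = enrichment.test_position_enrichment(
        table, config.min_orfs, config.alpha
    )
    positions.to_csv(outputs["positions"], sep="\t")

    families = enrichment.test_family_enrichment(
        membership,
        analysed,
        annotations=categories,
        leading_range=config.leading_range,
        min_size=config.family_min_size,
        alpha=config.alpha,
    )
    families.to_csv(outputs["families"], sep="\t")

    # ---- islands ----------------------------------------------------------
    stage = "islands"
    all_islands = []
    for cid in sorted(geometries):
        all_islands.extend(
            islands_mod.detect_islands(
                geometries[cid],
                categories,
                max_gap=config.island_max_gap,
                min_members=config.island_min_members,
            )
        )
    islands_mod.write_islands(
        all_islands, geometries, categories, outputs["islands"], outputs["islands_json"]
    )

    # ---- Frpo scan --------------------------------------------------------
    stage = "frpo"
    candidates = []
    if sequences:
        known = _read_fasta(config.known_frpo) if config.known_frpo else {}
        scheme = ScoringScheme(word_size=config.word_size, min_raw_score=config.min_raw_score)
        genes_by_contig: dict[str, list[GeneRecord]] = {}
        for g in genes:
            genes_by_contig.setdefault(g.contig_id, []).append(g)
        for cid in sorted(geometries):
            if cid not in sequences:
                continue
            regions = frpo_scan.extract_upstream_regions(
                geometries[cid],
                genes_by_contig[cid],
                sequences[cid],
                config.region_len_min,
                config.region_len_max,
            )
            for region in regions:
                candidates.append(frpo_scan.scan_region(region, known, scheme))
    frpo_scan.write_frpo_table(candidates, outputs["frpo"])

    # ---- manifest ---------------------------------------------------------
    params = {"version": __version__, "parameters": RunConfig.to_dict(config)}
    params["parameter_hash"] = hashlib.sha256(
        json.dumps(params["parameters"], sort_keys=True).encode()
    ).hexdigest()
    params["n_contigs_pass"] = len(geometries)
    params["n_contigs_rejected"] = len(rejected)
    outputs["manifest"].write_text(json.dumps(params, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        config=config,
        geometries=geometries,
        categories=categories,
        rejected=rejected,
        dedup=dedup_result,
        positions=positions,
        families=families,
        islands=all_islands,
        frpo_candidates=candidates,
        outputs=outputs,
    )


def report_positions(positions, min_sequences: int = 500):
    """Display filter: keep rows backed by at least ``min_sequences`` ORFs.

    Statistics are computed on the full table; this only trims the report.
    """
    out = positions[positions["n_total"] >= min_sequences]
    if out.empty:
        log.warning("no positions with at least %d sequences to report", min_sequences)
    return out
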