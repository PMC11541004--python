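"""Self-contained simulator with planted ground truth for every pipeline stage.

Emits exactly the dialects the readers consume (GFF3, FASTA, blast6 TSV,
tblout-like TSV, membership TSV) plus a truth JSON.  Each simulated contig
carries one relaxase gene adjacent to one planted oriT (copied, optionally
mutated, from the bundled stand-in oriT query set); leading positions 0..27
receive anti-defence labels at an enriched frequency versus the background
elsewhere; anti-defence cargo is placed in the T-strand-expressible
orientation with configurable probability.  Optional extras: redundant
duplicate contig groups, explicit anti-defence islands terminated by a
umu-like operon, and Frpo-like elements planted in upstream intergenic
regions.  Intergenic background sequence is i.i.d. uniform A/C/G/T.

Everything is deterministic given the (mandatory) seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from ._seq import revcomp
from .geometry import ContigInput
from .io_formats import (
    ANTI_DEFENCE_CATEGORIES,
    CategoryMap,
    GeneRecord,
    HomologyHit,
    assign_ordinals,
    write_blast6,
    write_category_map,
)

NUCLEOTIDES = np.array(list("ACGT"))

#: categories that travel on the T-strand when t_strand_prob = 1
CARGO_CATEGORIES = ANTI_DEFENCE_CATEGORIES + ("mtase", "ssb", "toxin_antitoxin")

ISLAND_CATEGORIES = ANTI_DEFENCE_CATEGORIES + ("mtase", "ssb", "toxin_antitoxin")


class SimConfigError(ValueError):
    """Impossible or invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator (all draws flow from ``seed``)."""

    seed: int
    n_contigs: int = 200
    genes_per_contig: tuple[int, int] = (40, 80)
    gene_length: tuple[int, int] = (300, 1200)
    intergenic_gap: tuple[int, int] = (20, 150)
    orit_length_jitter: float = 0.0
    orit_relaxase_gap: tuple[int, int] = (50, 800)
    orit_mutation_rate: float = 0.02
    leading_positions: int = 28
    leading_freq: float = 0.20
    background_freq: float = 0.01
    other_category_freqs: tuple[tuple[str, float], ...] = (
        ("mtase", 0.01),
        ("ssb", 0.01),
        ("toxin_antitoxin", 0.01),
        ("transposase", 0.01),
        ("umu_like", 0.005),
        ("other", 0.25),
    )
    t_strand_prob: float = 1.0
    umu_opposite_prob: float = 0.9
    island_prob: float = 0.0
    island_size: tuple[int, int] = (5, 8)
    dup_groups: int = 0
    dup_copies: int = 1
    dup_mutation: float = 0.0
    frpo_per_contig: int = 0
    frpo_tier: str = "frpo_prime"
    frpo_region_length: int = 120
    cluster_pool: int = 5000
    families_per_category: int = 4
    mob_types: tuple[str, ...] = ("MOB_F", "MOB_P1", "MOB_Q", "MOB_V", "MOB_H", "MOB_B")
    emit_sequences: bool = True

    def __post_init__(self) -> None:
        for name in ("leading_freq", "background_freq", "t_strand_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if self.genes_per_contig[0] < 4:
            raise SimConfigError("need at least 4 genes per contig")
        if self.frpo_region_length < 90 or self.frpo_region_length > 350:
            raise SimConfigError("frpo_region_length must be in [90, 350]")


@dataclass
class TruthTable:
    """Planted ground truth, kept consistent with the emitted files."""

    leading_direction: dict[str, int] = field(default_factory=dict)
    orit_interval: dict[str, tuple[int, int]] = field(default_factory=dict)
    category: dict[str, str] = field(default_factory=dict)  # gene_id -> category
    relative_position: dict[str, int] = field(default_factory=dict)
    t_strand_expressible: dict[str, bool] = field(default_factory=dict)
    duplicate_group: dict[str, str] = field(default_factory=dict)
    frpo_loci: list[dict] = field(default_factory=list)
    mob_type: dict[str, str] = field(default_factory=dict)
    enriched_positions: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["orit_interval"] = {k: list(v) for k, v in self.orit_interval.items()}
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SimulatedDataset:
    config: SimConfig
    genes: list[GeneRecord]
    sequences: dict[str, str]
    orit_hits: list[HomologyHit]
    relaxase_hits: list[HomologyHit]
    function_hits: list[HomologyHit]
    category_map: CategoryMap
    membership: dict[str, str]
    truth: TruthTable

    def contig_ids(self) -> list[str]:
        return sorted({g.contig_id for g in self.genes})

    def genes_of(self, contig_id: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.contig_id == contig_id]

    def contig_inputs(self) -> list[ContigInput]:
        """Bundle the dataset the way the pipeline's QC stage consumes it."""
        by_contig: dict[str, ContigInput] = {}
        for cid in self.contig_ids():
            by_contig[cid] = ContigInput(
                contig_id=cid,
                genes=[],
                relaxase_gene_ids=[],
                orit_hits=[],
                mob_type=self.truth.mob_type.get(cid),
                sequence=self.sequences.get(cid),
            )
        for g in self.genes:
            by_contig[g.contig_id].genes.append(g)
        gene_contig = {g.gene_id: g.contig_id for g in self.genes}
        for h in self.relaxase_hits:
            cid = gene_contig.get(h.subject_id)
            if cid is not None:
                by_contig[cid].relaxase_gene_ids.append(h.subject_id)
        for h in self.orit_hits:
            if h.subject_id in by_contig:
                by_contig[h.subject_id].orit_hits.append(h)
        return [by_contig[cid] for cid in sorted(by_contig)]

    def contig_table(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g in self.genes:
            out.setdefault(g.contig_id, []).append(g.gene_id)
        return out

    # ----- file emission ---------------------------------------------------

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {name: outdir / fname for name, fname in FILE_NAMES.items()}

        with open(paths["genes"], "w") as fh:
            fh.write("##gff-version 3\n")
            for g in sorted(self.genes, key=lambda g: (g.contig_id, g.start, g.gene_id)):
                fh.write(
                    f"{g.contig_id}\tleadscan_sim\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t0\tID={g.gene_id}\n"
                )
        if self.sequences:
            records = [
                SeqRecord(Seq(self.sequences[cid]), id=cid, description="")
                for cid in sorted(self.sequences)
            ]
            SeqIO.write(records, str(paths["fasta"]), "fasta")
        write_blast6(self.orit_hits, paths["orit_hits"])
        _write_tblout(self.relaxase_hits, paths["relaxase_hits"])
        _write_tblout(self.function_hits, paths["function_hits"])
        write_category_map(self.category_map, paths["category_map"])
        with open(paths["membership"], "w") as fh:
            fh.write("gene_id\tcluster_id\n")
            for gid in sorted(self.membership):
                fh.write(f"{gid}\t{self.membership[gid]}\n")
        with open(paths["mob"], "w") as fh:
            fh.write("contig_id\tmob_type\n")
            for cid in sorted(self.truth.mob_type):
                fh.write(f"{cid}\t{self.truth.mob_type[cid]}\n")
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


FILE_NAMES = {
    "genes": "genes.gff3",
    "fasta": "contigs.fasta",
    "orit_hits": "orit_hits.tsv",
    "relaxase_hits": "relaxase_hits.tblout",
    "function_hits": "function_hits.tblout",
    "category_map": "category_map.tsv",
    "membership": "membership.tsv",
    "mob": "mob_types.tsv",
    "truth": "truth.json",
}


def _write_tblout(hits, path) -> None:
    with open(path, "w") as fh:
        fh.write("# target\t-\tquery\t-\tevalue\tscore\n")
        for h in hits:
            fh.write(f"{h.subject_id} - {h.query_id} - {h.e_value:.3g} {h.bit_score:.1f}\n")


# ---------------------------------------------------------------------------
# bundled stand-in query sets
# ---------------------------------------------------------------------------


def _read_fasta_text(text: str) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def load_orit_standins() -> dict[str, str]:
    """Bundled synthetic stand-in oriT query set (not a real database)."""
    text = resources.files("leadscan.data").joinpath("orit_queries_synthetic.fasta").read_text()
    return _read_fasta_text(text)


def load_frpo_standins() -> dict[str, str]:
    """Bundled synthetic stand-in known-Frpo/ssi query set."""
    text = resources.files("leadscan.data").joinpath("frpo_known_synthetic.fasta").read_text()
    return _read_fasta_text(text)


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(NUCLEOTIDES[rng.integers(0, 4, size=length)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            options = [c for c in "ACGT" if c != chars[i]]
            chars[i] = options[rng.integers(0, 3)]
    return "".join(chars)


def _mutate_exact(seq: str, n_changes: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    positions = rng.choice(len(chars), size=n_changes, replace=False)
    for p in positions:
        options = [c for c in "ACGT" if c != chars[p]]
        chars[p] = options[rng.integers(0, 3)]
    return "".join(chars)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 200) -> str:
    """Shuffle preserving dinucleotide counts (random Eulerian walk)."""
    if len(seq) < 3:
        return seq
    for _ in range(max_tries):
        edges: dict[str, list[str]] = {}
        for a, b in zip(seq, seq[1:]):
            edges.setdefault(a, []).append(b)
        for a in edges:
            rng.shuffle(edges[a])
        walk = [seq[0]]
        node = seq[0]
        total = len(seq) - 1
        for _ in range(total):
            nxt_list = edges.get(node)
            if not nxt_list:
                break
            nxt = nxt_list.pop()
            walk.append(nxt)
            node = nxt
        if len(walk) == len(seq):
            return "".join(walk)
    out = list(seq)  # degenerate composition: fall back to mononucleotide shuffle
    rng.shuffle(out)
    return "".join(out)


# ---------------------------------------------------------------------------
# Frpo element construction
# ---------------------------------------------------------------------------

MINUS35 = "TTGACA"
MINUS10 = "TATAAT"


def plant_frpo(
    region_length: int,
    tier_target: str,
    rng: np.random.Generator,
    known_frpo: dict[str, str] | None = None,
) -> tuple[str, dict]:
    """Construct a regulatory region containing an Frpo-like element.

    Layout (5'->3'): pad, AT-rich UP element (20 nt), -35 hexamer, 17 nt
    spacer, -10 hexamer, 4 nt loop, reverse complement of the -35..-10
    block (a perfect stem over the elements), pad.  ``tier_target``
    controls the hexamer mismatches injected: ``frpo_prime`` at most one
    per hexamer, ``frpo_star`` two per hexamer, ``frpo`` embeds a mutated
    copy of a bundled known stand-in instead, ``none`` emits a
    dinucleotide-shuffled version of a prime construct.
    """
    if tier_target == "frpo":
        pool = known_frpo or load_frpo_standins()
        qid = sorted(pool)[rng.integers(0, len(pool))]
        core = _mutate(pool[qid], 0.05, rng)
        if len(core) > region_length:
            core = core[:region_length]
        pad = region_length - len(core)
        left = int(rng.integers(0, pad + 1)) if pad else 0
        seq = _random_seq(rng, left) + core + _random_seq(rng, pad - left)
        return seq, {"tier": "frpo", "query": qid}

    if tier_target == "none":
        seq, info = plant_frpo(region_length, "frpo_prime", rng, known_frpo)
        return dinucleotide_shuffle(seq, rng), {"tier": "none"}

    if tier_target == "frpo_prime":
        mm35 = int(rng.integers(0, 2))
        mm10 = int(rng.integers(0, 2 - mm35)) if mm35 < 2 else 0
    elif tier_target == "frpo_star":
        mm35, mm10 = 2, 2
    else:
        raise SimConfigError(f"unknown tier target {tier_target!r}")

    up = "".join(
        "AT"[rng.integers(0, 2)] if rng.random() < 0.9 else "GC"[rng.integers(0, 2)]
        for _ in range(20)
    )
    m35 = _mutate_exact(MINUS35, mm35, rng) if mm35 else MINUS35
    m10 = _mutate_exact(MINUS10, mm10, rng) if mm10 else MINUS10
    spacer = _random_seq(rng, 17)
    loop = _random_seq(rng, 4)
    block = m35 + spacer + m10
    stem = revcomp(block)
    core = up + block + loop + stem
    pad = region_length - len(core)
    if pad < 0:
        raise SimConfigError("region_length too short for Frpo construct")
    left = int(rng.integers(2, max(3, pad - 1))) if pad > 3 else 0
    seq = _random_seq(rng, left) + core + _random_seq(rng, pad - left)
    off35 = left + 20
    off10 = off35 + 6 + 17
    return seq, {
        "tier": tier_target,
        "minus35_offset": off35,
        "minus10_offset": off10,
        "mm35": mm35,
        "mm10": mm10,
    }


# ---------------------------------------------------------------------------
# contig simulation
# ---------------------------------------------------------------------------


@dataclass
class _ContigDraft:
    cid: str
    length: int
    genes: list[GeneRecord]
    categories: dict[str, str]
    relative_position: dict[str, int]
    expressible: dict[str, bool]
    relaxase_gene: str
    orit_interval: tuple[int, int]
    orit_query: str
    orit_pident: float
    orit_strand: str
    leading_direction: int
    mob: str
    fills: list[tuple[int, str]]  # (contig offset, sequence to splice)
    frpo_loci: list[dict]


def _draw_category(rng, config: SimConfig, in_leading_window: bool) -> str:
    anti_p = config.leading_freq if in_leading_window else config.background_freq
    r = rng.random()
    if r < anti_p:
        return ANTI_DEFENCE_CATEGORIES[rng.integers(0, 3)]
    r -= anti_p
    for cat, p in config.other_category_freqs:
        if r < p:
            return cat
        r -= p
    return "uncharacterized"


def _simulate_contig(cid: str, config: SimConfig, rng: np.random.Generator,
                     orit_pool: dict[str, str]) -> _ContigDraft:
    g_lo, g_hi = config.genes_per_contig
    n_genes = int(rng.integers(g_lo, g_hi + 1))
    n_lag = max(2, int(round(n_genes * rng.uniform(0.3, 0.6))))
    n_lead = n_genes - n_lag
    if n_lead < 2:
        n_lead = 2
        n_lag = n_genes - n_lead
    mob = config.mob_types[rng.integers(0, len(config.mob_types))]

    orit_query = sorted(orit_pool)[rng.integers(0, len(orit_pool))]
    orit_seq = _mutate(orit_pool[orit_query], config.orit_mutation_rate, rng)
    orit_pident = 100.0 * sum(
        a == b for a, b in zip(orit_seq, orit_pool[orit_query])
    ) / len(orit_seq)

    # choose categories up-front: lagging genes (relpos -n_lag..-1), relaxase at -1
    relpos_sequence = list(range(-n_lag, 0)) + list(range(0, n_lead))
    categories: dict[int, str] = {}
    for rp in relpos_sequence:
        if rp == -1:
            categories[rp] = "relaxase"
        else:
            in_window = 0 <= rp < config.leading_positions
            categories[rp] = _draw_category(rng, config, in_window)

    # optional explicit island with a terminating umu-like operon
    island = rng.random() < config.island_prob
    if island:
        size = int(rng.integers(config.island_size[0], config.island_size[1] + 1))
        size = min(size, n_lead - 3)
        for rp in range(size):
            categories[rp] = ISLAND_CATEGORIES[rng.integers(0, len(ISLAND_CATEGORIES))]
        if size + 1 < n_lead:
            categories[size] = "umu_like"
            categories[size + 1] = "umu_like"

    # Frpo planting targets: expressible leading genes away from the edges
    frpo_targets: list[int] = []
    if config.frpo_per_contig > 0:
        eligible = [rp for rp in range(1, n_lead - 1)]
        rng.shuffle(eligible)
        frpo_targets = sorted(eligible[: config.frpo_per_contig])

    # strand per relpos in the canonical (+1 leading direction) frame:
    # expressible genes point against the leading direction, i.e. '-'
    strands: dict[int, str] = {}
    expressible_truth: dict[int, bool] = {}
    for rp in relpos_sequence:
        cat = categories[rp]
        if rp in frpo_targets:
            expressible = True
        elif cat in CARGO_CATEGORIES:
            expressible = rng.random() < config.t_strand_prob
        elif cat == "umu_like":
            expressible = not (rng.random() < config.umu_opposite_prob)
        else:
            expressible = rng.random() < 0.5
        strands[rp] = "-" if expressible else "+"
        expressible_truth[rp] = expressible

    # lay features left -> right; gene at relpos -1 is the relaxase
    genes: list[GeneRecord] = []
    fills: list[tuple[int, str]] = []
    frpo_loci: list[dict] = []
    x = int(rng.integers(*config.intergenic_gap))
    gene_coords: dict[int, tuple[int, int]] = {}
    upstream_fill_after: dict[int, int] = {}

    for rp in range(-n_lag, 0):
        length = int(rng.integers(*config.gene_length))
        gene_coords[rp] = (x, x + length)
        x += length
        if rp == -1:
            break
        x += int(rng.integers(*config.intergenic_gap))

    x += int(rng.integers(*config.orit_relaxase_gap))
    orit_interval = (x, x + len(orit_seq))
    fills.append((x, orit_seq))
    x = orit_interval[1]

    for rp in range(0, n_lead):
        x += int(rng.integers(*config.intergenic_gap))
        length = int(rng.integers(*config.gene_length))
        gene_coords[rp] = (x, x + length)
        x += length
        if rp in frpo_targets:
            # the gene is on '-' in this frame: its regulatory region is the
            # intergenic span to its right, read on the reverse complement
            region, info = plant_frpo(config.frpo_region_length, config.frpo_tier, rng)
            fills.append((x, revcomp(region)))
            frpo_loci.append(
                {
                    "relpos": rp,
                    "region_interval": (x, x + len(region)),
                    **info,
                }
            )
            x += len(region)
    x += int(rng.integers(*config.intergenic_gap))
    total_len = x

    gene_ids: dict[int, str] = {}
    for k, rp in enumerate(relpos_sequence):
        gid = f"{cid}_g{k:03d}"
        gene_ids[rp] = gid
        s, e = gene_coords[rp]
        genes.append(GeneRecord(cid, s, e, strands[rp], gid))

    # mirror half of the contigs so leading direction -1 is exercised
    leading_direction = 1
    orit_iv = orit_interval
    orit_strand = "+"
    if rng.random() < 0.5:
        leading_direction = -1
        L = total_len
        for g in genes:
            g.start, g.end = L - g.end, L - g.start
            g.strand = "+" if g.strand == "-" else "-"
        orit_iv = (L - orit_interval[1], L - orit_interval[0])
        orit_strand = "-"
        fills = [(L - (off + len(seq)), revcomp(seq)) for off, seq in fills]
        for locus in frpo_loci:
            s, e = locus["region_interval"]
            locus["region_interval"] = (L - e, L - s)

    for locus in frpo_loci:
        locus["gene_id"] = gene_ids[locus.pop("relpos")]
        locus["contig_id"] = cid
        locus["region_interval"] = list(locus["region_interval"])

    return _ContigDraft(
        cid=cid,
        length=total_len,
        genes=genes,
        categories={gene_ids[rp]: categories[rp] for rp in relpos_sequence},
        relative_position={gene_ids[rp]: rp for rp in relpos_sequence},
        expressible={gene_ids[rp]: expressible_truth[rp] for rp in relpos_sequence},
        relaxase_gene=gene_ids[-1],
        orit_interval=orit_iv,
        orit_query=orit_query,
        orit_pident=orit_pident,
        orit_strand=orit_strand,
        leading_direction=leading_direction,
        mob=mob,
        fills=fills,
        frpo_loci=frpo_loci,
    )


def _duplicate_draft(draft: _ContigDraft, new_cid: str) -> _ContigDraft:
    mapping = {g.gene_id: g.gene_id.replace(draft.cid, new_cid, 1) for g in draft.genes}
    genes = [
        GeneRecord(new_cid, g.start, g.end, g.strand, mapping[g.gene_id])
        for g in draft.genes
    ]
    return replace(
        draft,
        cid=new_cid,
        genes=genes,
        categories={mapping[g]: c for g, c in draft.categories.items()},
        relative_position={mapping[g]: p for g, p in draft.relative_position.items()},
        expressible={mapping[g]: e for g, e in draft.expressible.items()},
        relaxase_gene=mapping[draft.relaxase_gene],
        frpo_loci=[
            {**loc, "gene_id": mapping[loc["gene_id"]], "contig_id": new_cid}
            for loc in draft.frpo_loci
        ],
    )


def _build_category_map(config: SimConfig) -> CategoryMap:
    mapping: dict[str, str] = {}
    for mob in config.mob_types:
        mapping[f"{mob}_relaxase_prof"] = "relaxase"
    mapping["traM_prof"] = "traM"
    cats = set(ANTI_DEFENCE_CATEGORIES) | {
        "mtase", "ssb", "toxin_antitoxin", "umu_like", "transposase", "mobility", "other"
    }
    for cat in sorted(cats):
        for v in range(3):
            mapping[f"prof_{cat}_{v}"] = cat
    return CategoryMap(mapping)


def simulate_contigs(config: SimConfig) -> SimulatedDataset:
    """Generate the full fixture (files writable via ``SimulatedDataset.write``)."""
    rng = np.random.default_rng(config.seed)
    orit_pool = load_orit_standins()
    category_map = _build_category_map(config)

    drafts: list[_ContigDraft] = []
    for idx in range(config.n_contigs):
        drafts.append(_simulate_contig(f"ctg{idx:04d}", config, rng, orit_pool))

    # duplicate groups: copy the first dup_groups drafts (dup_copies total each)
    dup_group_of: dict[str, str] = {}
    n_base = len(drafts)
    if config.dup_groups > 0 and config.dup_copies > 1:
        if config.dup_groups > n_base:
            raise SimConfigError("more duplicate groups than contigs")
        extras: list[_ContigDraft] = []
        for gi in range(config.dup_groups):
            seed_draft = drafts[gi]
            group = f"dup{gi:03d}"
            dup_group_of[seed_draft.cid] = group
            for ci in range(1, config.dup_copies):
                extras.append(_duplicate_draft(seed_draft, f"ctg{n_base + len(extras):04d}"))
                dup_group_of[extras[-1].cid] = group
        drafts.extend(extras)

    genes: list[GeneRecord] = []
    sequences: dict[str, str] = {}
    orit_hits: list[HomologyHit] = []
    relaxase_hits: list[HomologyHit] = []
    function_hits: list[HomologyHit] = []
    membership: dict[str, str] = {}
    truth = TruthTable(enriched_positions=list(range(config.leading_positions)))

    cluster_serial = 0
    for draft in drafts:
        genes.extend(draft.genes)
        truth.leading_direction[draft.cid] = draft.leading_direction
        truth.orit_interval[draft.cid] = draft.orit_interval
        truth.mob_type[draft.cid] = draft.mob
        truth.category.update(draft.categories)
        truth.relative_position.update(draft.relative_position)
        truth.t_strand_expressible.update(draft.expressible)
        truth.frpo_loci.extend(draft.frpo_loci)
        if draft.cid in dup_group_of:
            truth.duplicate_group[draft.cid] = dup_group_of[draft.cid]

        orit_hits.append(
            HomologyHit(
                query_id=draft.orit_query,
                subject_id=draft.cid,
                sstart=draft.orit_interval[0],
                send=draft.orit_interval[1],
                strand=draft.orit_strand,
                percent_identity=draft.orit_pident,
                bit_score=round(draft.orit_pident, 1),
                e_value=1e-40,
            )
        )
        relaxase_hits.append(
            HomologyHit(
                query_id=f"{draft.mob}_relaxase_prof",
                subject_id=draft.relaxase_gene,
                bit_score=float(200 + rng.integers(0, 200)),
                e_value=1e-30,
            )
        )
        for g in draft.genes:
            cat = draft.categories[g.gene_id]
            if cat not in ("uncharacterized", "relaxase"):
                function_hits.append(
                    HomologyHit(
                        query_id=f"prof_{cat}_{rng.integers(0, 3)}",
                        subject_id=g.gene_id,
                        bit_score=float(50 + rng.integers(0, 150)),
                        e_value=10.0 ** -float(rng.integers(10, 40)),
                    )
                )

    # cluster membership: duplicates of a contig share clusters gene-by-gene;
    # anti-defence genes join a small number of recurring families; the rest
    # draw from a large cluster pool so chance overlap stays negligible
    base_cluster: dict[tuple[str, int], str] = {}
    for draft in drafts:
        src = dup_group_of.get(draft.cid)
        for g in draft.genes:
            rp = draft.relative_position[g.gene_id]
            if src is not None and (src, rp) in base_cluster:
                cluster = base_cluster[(src, rp)]
                if config.dup_mutation > 0 and rng.random() < config.dup_mutation:
                    cluster = f"mut{cluster_serial:07d}"
                    cluster_serial += 1
            else:
                cat = draft.categories[g.gene_id]
                if cat in ANTI_DEFENCE_CATEGORIES or cat in ("mtase", "ssb", "toxin_antitoxin", "umu_like"):
                    fam = rng.integers(0, config.families_per_category)
                    cluster = f"fam_{cat}_{fam}"
                else:
                    cluster = f"clu{rng.integers(0, config.cluster_pool):05d}"
                if src is not None:
                    base_cluster[(src, rp)] = cluster
            membership[g.gene_id] = cluster

    genes = assign_ordinals(genes)

    if config.emit_sequences:
        for draft in drafts:
            arr = NUCLEOTIDES[rng.integers(0, 4, size=draft.length)]
            seq = "".join(arr)
            for off, fill in sorted(draft.fills):
                seq = seq[:off] + fill + seq[off + len(fill):]
            sequences[draft.cid] = seq

    return SimulatedDataset(
        config=config,
        genes=genes,
        sequences=sequences,
        orit_hits=orit_hits,
        relaxase_hits=relaxase_hits,
        function_hits=function_hits,
        category_map=category_map,
        membership=membership,
        truth=truth,
    )


def simulate_null(config: SimConfig) -> SimulatedDataset:
    """Fixture with no positional structure (type-I-error harness)."""
    flat = replace(
        config,
        leading_freq=config.background_freq,
        island_prob=0.0,
        frpo_per_contig=0,
    )
    ds = simulate_contigs(flat)
    ds.truth.enriched_positions = []
    return ds
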