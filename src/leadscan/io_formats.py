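"""Readers/writers for the external formats the pipeline consumes and emits.

Internal convention: all coordinates are 0-based half-open on the + strand of
the contig.  GFF3 (1-based closed) and BLAST tabular (1-based inclusive, with
subject start > end encoding the minus strand) are converted at the boundary.

Supported dialects
------------------
* gene annotations: GFF3 or the internal gene-table TSV
  (``contig_id  gene_id  start  end  strand  ordinal  category``)
* homology hits: BLAST outfmt-6 (12 standard columns) and HMMER3 ``tblout``
  (full-sequence e-value/score columns)
* category maps: two-column TSV ``profile_id  category``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

#: Functional categories a profile may map to.
CATEGORIES = frozenset(
    {
        "anti_crispr",
        "anti_restriction",
        "sos_inhibitor",
        "mtase",
        "ssb",
        "toxin_antitoxin",
        "mobility",
        "transposase",
        "umu_like",
        "relaxase",
        "traM",
        "other",
        "uncharacterized",
    }
)

#: The three categories pooled as "anti-defence" in positional statistics.
ANTI_DEFENCE_CATEGORIES = ("anti_crispr", "anti_restriction", "sos_inhibitor")


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed values violate an invariant (e.g. end <= start)."""


@dataclass(slots=True)
class GeneRecord:
    """One ORF on a contig.

    ``ordinal`` is the 0-based rank of the gene along the contig by start
    coordinate (ties broken by end, then gene_id).
    """

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    ordinal: int = -1
    category: str = "uncharacterized"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(slots=True)
class HomologyHit:
    """A filtered homology hit (protein pHMM hit or nucleotide BLAST hit).

    For protein (tblout) hits the subject is a gene id and the interval is
    unused (0, 0 sentinel).  For nucleotide hits the subject is a contig and
    the interval is 0-based half-open on the + strand.
    """

    query_id: str
    subject_id: str
    sstart: int = 0
    send: int = 0
    strand: str = "+"
    percent_identity: float = float("nan")
    bit_score: float = 0.0
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: e_value < 0")
        if (self.sstart, self.send) != (0, 0) and not 0 <= self.sstart < self.send:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: bad interval"
            )


class CategoryMap:
    """Mapping of profile/query ids to functional categories."""

    def __init__(self, mapping: Mapping[str, str]):
        bad = {c for c in mapping.values() if c not in CATEGORIES}
        if bad:
            raise ValidationError(f"unknown categories: {sorted(bad)}")
        self._map = dict(mapping)

    def __getitem__(self, profile_id: str) -> str:
        return self._map[profile_id]

    def __contains__(self, profile_id: str) -> bool:
        return profile_id in self._map

    def get(self, profile_id: str, default: str | None = None) -> str | None:
        return self._map.get(profile_id, default)

    def items(self):
        return self._map.items()

    def __len__(self) -> int:
        return len(self._map)


def read_category_map(path: str | Path) -> CategoryMap:
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        if parts[0] in mapping and mapping[parts[0]] != parts[1]:
            raise ValidationError(f"{path}:{lineno}: profile {parts[0]} mapped twice")
        mapping[parts[0]] = parts[1]
    return CategoryMap(mapping)


def write_category_map(cmap: CategoryMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, cat in sorted(cmap.items()):
            fh.write(f"{pid}\t{cat}\n")


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

GENE_TABLE_COLUMNS = ("contig_id", "gene_id", "start", "end", "strand", "ordinal", "category")


def assign_ordinals(genes: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Sort genes and assign consecutive per-contig ordinals by start position."""
    out: list[GeneRecord] = []
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    for contig_id in sorted(by_contig):
        recs = sorted(by_contig[contig_id], key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(recs):
            g.ordinal = i
        out.extend(recs)
    return out


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


_GFF_FEATURES = {"CDS", "gene", "ORF"}


def read_gene_annotations(
    path: str | Path, contig_id: str | None = None, fmt: str | None = None
) -> list[GeneRecord]:
    """Read gene records from GFF3 or the internal TSV gene table.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open.
    Records are returned sorted with per-contig ordinals assigned.  ``fmt``
    may be ``"gff3"`` or ``"tsv"``; by default it is sniffed from the header.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if fmt is None:
        if path.suffix.lower() in (".gff", ".gff3") or text.startswith("##gff"):
            fmt = "gff3"
        elif lines and lines[0].startswith("contig_id\t"):
            fmt = "tsv"
        else:
            fmt = "gff3"

    genes: list[GeneRecord] = []
    if fmt == "gff3":
        counter = 0
        for lineno, line in enumerate(lines, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = parts
            if ftype not in _GFF_FEATURES:
                continue
            if contig_id is not None and seqid != contig_id:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise ValidationError(f"{path}:{lineno}: invalid GFF3 interval {start1}..{end1}")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: strand must be + or -")
            attr = _parse_gff3_attributes(attrs)
            gid = attr.get("ID") or attr.get("locus_tag") or f"{seqid}_orf{counter}"
            counter += 1
            genes.append(GeneRecord(seqid, start1 - 1, end1, strand, gid))
    elif fmt == "tsv":
        genes = read_gene_table(path, contig_id=contig_id)
        return genes
    else:
        raise ValueError(f"unknown gene annotation format: {fmt}")

    if not genes:
        log.warning("no gene records parsed from %s", path)
    return assign_ordinals(genes)


def read_gene_table(path: str | Path, contig_id: str | None = None) -> list[GeneRecord]:
    """Read the internal TSV gene table (round-trip partner of write_gene_table)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        log.warning("empty gene table %s", path)
        return []
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != GENE_TABLE_COLUMNS:
        raise ParseError(f"{path}:1: unexpected gene-table header {header}")
    genes = []
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(GENE_TABLE_COLUMNS):
            raise ParseError(f"{path}:{lineno}: expected {len(GENE_TABLE_COLUMNS)} columns")
        cid, gid, start_s, end_s, strand, ord_s, cat = parts
        if contig_id is not None and cid != contig_id:
            continue
        genes.append(GeneRecord(cid, int(start_s), int(end_s), strand, gid, int(ord_s), cat))
    return genes


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.contig_id}\t{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t"
                f"{g.ordinal}\t{g.category}\n"
            )


# ---------------------------------------------------------------------------
# homology hits
# ---------------------------------------------------------------------------

DEFAULT_EVALUE_THRESHOLD = 1e-6


def read_homology_hits(
    path: str | Path,
    kind: str,
    e_threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> list[HomologyHit]:
    """Parse a BLAST outfmt-6 (``blast6``) or HMMER3 ``hmm_tblout`` table.

    Hits with e-value above ``e_threshold`` are dropped (count logged).
    blast6 subject coordinates with start > end are normalized to a
    forward-strand half-open interval with strand ``-``.
    """
    if kind not in ("blast6", "hmm_tblout"):
        raise ValueError(f"unknown hit-table kind: {kind}")
    hits: list[HomologyHit] = []
    dropped = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        if kind == "blast6":
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 12:
                raise ParseError(f"{path}:{lineno}: expected 12 blast6 columns, got {len(parts)}")
            (qseqid, sseqid, pident, length, _mm, _go, _qs, _qe, sstart_s, send_s,
             evalue_s, bits_s) = parts
            try:
                s1, s2 = int(sstart_s), int(send_s)
                evalue, bits, pident_f = float(evalue_s), float(bits_s), float(pident)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric field") from exc
            if s1 <= s2:
                strand, sstart, send = "+", s1 - 1, s2
            else:
                strand, sstart, send = "-", s2 - 1, s1
            hit = HomologyHit(qseqid, sseqid, sstart, send, strand, pident_f, bits, evalue)
        else:  # hmm_tblout: whitespace separated, full-sequence columns 5/6
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: truncated tblout line")
            target, _tacc, query, _qacc, evalue_s, score_s = parts[:6]
            try:
                evalue, score = float(evalue_s), float(score_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric field") from exc
            hit = HomologyHit(query, target, bit_score=score, e_value=evalue)
        if hit.e_value > e_threshold:
            dropped += 1
            continue
        hits.append(hit)
    if dropped:
        log.info("dropped %d hits above e-value threshold %g from %s", dropped, e_threshold, path)
    return hits


def write_blast6(hits: Sequence[HomologyHit], path: str | Path) -> None:
    """Write hits in blast6 layout so internal and external searches interchange."""
    with open(path, "w") as fh:
        for h in hits:
            length = h.send - h.sstart
            if h.strand == "+":
                s1, s2 = h.sstart + 1, h.send
            else:
                s1, s2 = h.send, h.sstart + 1
            pid = 0.0 if h.percent_identity != h.percent_identity else h.percent_identity
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{pid:.2f}\t{length}\t0\t0\t1\t{length}\t"
                f"{s1}\t{s2}\t{h.e_value:.3g}\t{h.bit_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# category assignment
# ---------------------------------------------------------------------------


def _hit_sort_key(hit: HomologyHit):
    # best bit score wins; ties -> lowest e-value, then lexicographic profile id
    return (-hit.bit_score, hit.e_value, hit.query_id)


def assign_categories(
    genes: Sequence[GeneRecord],
    hits: Iterable[HomologyHit],
    category_map: CategoryMap,
) -> list[GeneRecord]:
    """Label each gene with the category of its best-scoring mapped hit.

    Protein-level hits are keyed by gene id; nucleotide hits whose subject is
    a contig id are attributed to the gene overlapping the hit interval.
    Genes without any qualifying hit stay ``uncharacterized``.  The result is
    independent of hit order.
    """
    by_gene_id = {g.gene_id: g for g in genes}
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)

    best: dict[str, HomologyHit] = {}
    for hit in sorted(hits, key=_hit_sort_key):
        if hit.query_id not in category_map:
            log.warning("hit query %s not in category map; skipped", hit.query_id)
            continue
        targets: list[str] = []
        if hit.subject_id in by_gene_id:
            targets = [hit.subject_id]
        elif hit.subject_id in by_contig and hit.send > hit.sstart:
            for g in by_contig[hit.subject_id]:
                if g.start < hit.send and hit.sstart < g.end:
                    targets.append(g.gene_id)
        else:
            log.warning("hit subject %s matches no gene or contig; skipped", hit.subject_id)
            continue
        for gid in targets:
            if gid not in best:  # hits are pre-sorted best-first
                best[gid] = hit

    out = []
    for g in genes:
        hit = best.get(g.gene_id)
        category = category_map[hit.query_id] if hit is not None else "uncharacterized"
        g.category = category
        out.append(g)
    return out
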