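"""Detection of Frpo/ssi single-strand promoters in upstream regulatory regions.

Frpo-type elements let RNA polymerase fire from single-stranded DNA: the
region folds back on itself so that the -35 (TTGACA) and -10 (TATAAT)
hexamers and the AT-rich UP element sit in a duplex stem that mimics
double-stranded promoter DNA.  Detection combines three lines of evidence:

1. homology to a set of known Frpo/ssi query sequences (via the package's
   short-word aligner);
2. a sigma70 consensus scan for -35/-10 hexamer pairs with a plausible
   spacer and an AT-rich UP window;
3. secondary-structure evidence from deterministic base-pair maximization
   (Nussinov-style, Watson-Crick + GT wobble, minimum loop 3) plus an
   explicit check that the element block has a complementary partner
   elsewhere in the region (a genuine stem, not incidental pairing).

Candidates are tiered: ``frpo`` (homology), ``frpo_prime`` (consensus with
at most 2 total hexamer mismatches plus stem evidence), ``frpo_star``
(up to 4 mismatches plus stem evidence) or ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._seq import revcomp
from .geometry import ContigGeometry
from .io_formats import GeneRecord
from .orit_search import (
    DEFAULT_SCHEME,
    AlignmentHit,
    ScoringScheme,
    local_align,
    seed_and_extend,
)

MINUS35 = "TTGACA"
MINUS10 = "TATAAT"
DEFAULT_SPACER = (15, 19)
DEFAULT_REGION_BOUNDS = (50, 350)
UP_WINDOW = 20
UP_AT_RICH = 0.75
MAX_FOLD_LENGTH = 400
STEM_SUPPORT_MIN_SCORE = 12

TIERS = ("none", "frpo_star", "frpo_prime", "frpo")


def tier_rank(tier: str) -> int:
    return TIERS.index(tier)


@dataclass(slots=True)
class UpstreamRegion:
    """A 50-350 bp intergenic span upstream of a leading-region gene.

    ``sequence`` is 5'->3' in the gene's coding orientation (i.e. reverse
    complemented for minus-strand genes); ``start``/``end`` stay in contig
    forward coordinates.
    """

    contig_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class PromoterElementHit:
    minus35_offset: int
    minus35_mismatches: int
    minus10_offset: int
    minus10_mismatches: int
    spacer: int
    up_at_fraction: float

    @property
    def total_mismatches(self) -> int:
        return self.minus35_mismatches + self.minus10_mismatches

    @property
    def up_at_rich(self) -> bool:
        return self.up_at_fraction >= UP_AT_RICH

    def element_positions(self) -> list[int]:
        return list(range(self.minus35_offset, self.minus35_offset + 6)) + list(
            range(self.minus10_offset, self.minus10_offset + 6)
        )


@dataclass(slots=True)
class BasePairStructure:
    """One optimal base-pair-maximization structure."""

    length: int
    pairs: list[tuple[int, int]]
    n_pairs: int

    def paired_positions(self) -> set[int]:
        out: set[int] = set()
        for i, j in self.pairs:
            out.add(i)
            out.add(j)
        return out

    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i], chars[j] = "(", ")"
        return "".join(chars)


@dataclass(slots=True)
class HairpinEvidence:
    paired_fraction: float
    stem_flag: bool  # paired fraction of element positions >= 0.5
    support_score: int  # best complementary-block alignment score
    supported: bool  # support_score >= STEM_SUPPORT_MIN_SCORE


@dataclass(slots=True)
class FrpoCandidate:
    region: UpstreamRegion
    tier: str
    homology: AlignmentHit | None = None
    element: PromoterElementHit | None = None
    hairpin: HairpinEvidence | None = None
    structure_score: int = 0
    dot_bracket: str = ""


# ---------------------------------------------------------------------------
# upstream region extraction
# ---------------------------------------------------------------------------


def extract_upstream_regions(
    geometry: ContigGeometry,
    genes: Sequence[GeneRecord],
    sequence: str,
    len_min: int = DEFAULT_REGION_BOUNDS[0],
    len_max: int = DEFAULT_REGION_BOUNDS[1],
    max_position: int | None = None,
) -> list[UpstreamRegion]:
    """Strand-aware intergenic spans upstream of leading-region genes.

    The span runs from the gene's (strand-aware) start back to the previous
    feature boundary (neighbouring gene or the oriT).  Spans shorter than
    ``len_min`` or longer than ``len_max`` are excluded.
    """
    if sequence is None:
        raise ValueError(f"missing sequence for contig {geometry.contig_id}")
    genes_by_id = {g.gene_id: g for g in genes}
    boundaries: list[tuple[int, int]] = [(g.start, g.end) for g in genes]
    if geometry.orit is not None:
        boundaries.append((geometry.orit.orit_start, geometry.orit.orit_end))

    out: list[UpstreamRegion] = []
    for gid in geometry.leading_genes(max_position):
        g = genes_by_id.get(gid)
        if g is None:
            continue
        if g.strand == "+":
            prev_ends = [e for s, e in boundaries if e <= g.start and (s, e) != (g.start, g.end)]
            lo = max(prev_ends, default=0)
            hi = g.start
            seq = sequence[lo:hi]
        else:
            next_starts = [
                s for s, e in boundaries if s >= g.end and (s, e) != (g.start, g.end)
            ]
            lo = g.end
            hi = min(next_starts, default=len(sequence))
            seq = revcomp(sequence[lo:hi])
        if not (len_min <= hi - lo <= len_max):
            continue
        out.append(UpstreamRegion(geometry.contig_id, gid, lo, hi, g.strand, seq.upper()))
    return out


# ---------------------------------------------------------------------------
# homology scan
# ---------------------------------------------------------------------------


def homology_scan(
    regions: Sequence[UpstreamRegion],
    known_frpo: Mapping[str, str],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> dict[str, AlignmentHit | None]:
    """Best alignment of each region against the known Frpo/ssi queries.

    Returns region gene_id -> best AlignmentHit (or None if no query scores
    at least ``scheme.min_raw_score``).
    """
    out: dict[str, AlignmentHit | None] = {}
    for region in regions:
        best: AlignmentHit | None = None
        for qid in sorted(known_frpo):
            hits = seed_and_extend(
                known_frpo[qid], region.sequence, scheme, query_id=qid,
                subject_id=region.gene_id,
            )
            for h in hits:
                if best is None or (h.raw_score, h.query_id) > (best.raw_score, best.query_id):
                    best = h
        out[region.gene_id] = best
    return out


# ---------------------------------------------------------------------------
# sigma70 consensus scan
# ---------------------------------------------------------------------------


def _mismatches(seq: str, consensus: str) -> int:
    return sum(a != b for a, b in zip(seq, consensus))


def scan_sigma70_elements(
    region: str,
    max_mm35: int = 2,
    max_mm10: int = 2,
    spacer: tuple[int, int] = DEFAULT_SPACER,
) -> list[PromoterElementHit]:
    """All -35/-10 hexamer pairs within the mismatch and spacer bounds.

    The UP-element AT fraction is computed over the 20 nt upstream of the
    -35 hexamer (truncated at the region start).
    """
    region = region.upper()
    if len(region) < 30:
        return []
    s_lo, s_hi = spacer
    hits: list[PromoterElementHit] = []
    for i in range(len(region) - 6 + 1):
        mm35 = _mismatches(region[i : i + 6], MINUS35)
        if mm35 > max_mm35:
            continue
        for sp in range(s_lo, s_hi + 1):
            j = i + 6 + sp
            if j + 6 > len(region):
                break
            mm10 = _mismatches(region[j : j + 6], MINUS10)
            if mm10 > max_mm10:
                continue
            up = region[max(0, i - UP_WINDOW) : i]
            at = (up.count("A") + up.count("T")) / len(up) if up else 0.0
            hits.append(PromoterElementHit(i, mm35, j, mm10, sp, at))
    return hits


def best_element(hits: Sequence[PromoterElementHit]) -> PromoterElementHit | None:
    """Fewest total mismatches; ties by AT-richer UP element, then leftmost."""
    if not hits:
        return None
    return min(
        hits, key=lambda h: (h.total_mismatches, -h.up_at_fraction, h.minus35_offset)
    )


# ---------------------------------------------------------------------------
# base-pair maximization (Nussinov-style)
# ---------------------------------------------------------------------------

_PAIRABLE = {
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
}


def _pair_matrix(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    n = len(seq)
    ok = np.zeros((n, n), dtype=bool)
    for a, b in _PAIRABLE:
        ok |= (codes[:, None] == ord(a)) & (codes[None, :] == ord(b))
    return ok


def max_basepairs(sequence: str, min_loop: int = 3) -> BasePairStructure:
    """Maximum number of nested base pairs (WC + GT wobble) with loop >= min_loop.

    The DP is filled by diagonals with the bifurcation term vectorized; the
    traceback is deterministic, preferring to pair (i, j) with the smallest
    i and largest j among optimal choices.  Refuses sequences longer than
    ``MAX_FOLD_LENGTH``.
    """
    n = len(sequence)
    if n > MAX_FOLD_LENGTH:
        raise ValueError(f"sequence length {n} exceeds folding cap {MAX_FOLD_LENGTH}")
    if n == 0:
        return BasePairStructure(0, [], 0)
    can_pair = _pair_matrix(sequence)
    dp = np.zeros((n, n), dtype=np.int32)

    for span in range(min_loop + 2, n + 1):  # spans that can hold >= 1 pair
        i = np.arange(0, n - span + 1)
        j = i + span - 1
        best = dp[i + 1, j]  # i unpaired
        # i paired with j (needs loop of >= min_loop when nothing between)
        paired = np.where(can_pair[i, j], dp[i + 1, j - 1] + 1, -1)
        best = np.maximum(best, paired)
        # bifurcation: split after offset t (i..i+t | i+t+1..j)
        if span >= 2:
            for t in range(0, span - 1):
                left = dp[i, i + t]
                right = dp[i + t + 1, j]
                best = np.maximum(best, left + right)
        dp[i, j] = best

    # traceback: prefer pairing the smallest-i position with its largest
    # optimal partner; leave i unpaired only when no pairing is optimal
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or dp[i, j] == 0:
            continue
        done = False
        for h in range(j, i + min_loop, -1):
            if not can_pair[i, h]:
                continue
            inner = dp[i + 1, h - 1]
            rest = dp[h + 1, j] if h + 1 <= j else 0
            if inner + 1 + rest == dp[i, j]:
                pairs.append((i, h))
                stack.append((h + 1, j))
                stack.append((i + 1, h - 1))
                done = True
                break
        if not done:
            stack.append((i + 1, j))
    pairs.sort()
    return BasePairStructure(n, pairs, int(dp[0, n - 1]))


def structure_from_dot_bracket(dot_bracket: str) -> BasePairStructure:
    """Build a structure from an external folder's dot-bracket string.

    Lets thermodynamic predictions (e.g. from an RNA/DNA folding tool) be
    plugged in wherever the internal base-pair maximization is used.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"unexpected character {c!r} in dot-bracket string")
    if stack:
        raise ValueError("unbalanced '(' in dot-bracket string")
    pairs.sort()
    return BasePairStructure(len(dot_bracket), pairs, len(pairs))


# ---------------------------------------------------------------------------
# hairpin evidence and classification
# ---------------------------------------------------------------------------


def stem_support_score(
    region: str, element: PromoterElementHit, scheme: ScoringScheme = DEFAULT_SCHEME
) -> int:
    """Best local-alignment score of the -35..-10 block vs the region's
    reverse complement outside the block — evidence of a real complementary
    partner for the element."""
    region = region.upper()
    block = region[element.minus35_offset : element.minus10_offset + 6]
    rest = region[: element.minus35_offset] + "N" * len(block) + region[element.minus10_offset + 6 :]
    aln = local_align(block, revcomp(rest), scheme)
    return aln.score


def hairpin_evidence(
    region: str,
    element: PromoterElementHit,
    structure: BasePairStructure,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> HairpinEvidence:
    """Fraction of the 12 element nucleotides paired in the optimal structure.

    ``stem_flag`` is true when at least half the element positions are
    paired; ``supported`` additionally requires a complementary block for
    the element elsewhere in the region (see ``stem_support_score``), since
    maximum-pairing structures of arbitrary sequences pair most positions.
    """
    paired = structure.paired_positions()
    positions = element.element_positions()
    frac = sum(p in paired for p in positions) / len(positions)
    support = stem_support_score(region, element, scheme)
    return HairpinEvidence(
        paired_fraction=frac,
        stem_flag=frac >= 0.5,
        support_score=support,
        supported=support >= STEM_SUPPORT_MIN_SCORE,
    )


def classify_candidate(
    homology: AlignmentHit | None,
    element: PromoterElementHit | None,
    hairpin: HairpinEvidence | None,
) -> str:
    """Tier a candidate: homology -> frpo; else consensus + stem evidence."""
    if homology is not None:
        return "frpo"
    if element is None or hairpin is None:
        return "none"
    stem_ok = hairpin.stem_flag and hairpin.supported
    if element.total_mismatches <= 2 and stem_ok:
        return "frpo_prime"
    if element.total_mismatches <= 4 and stem_ok:
        return "frpo_star"
    return "none"


def scan_region(
    region: UpstreamRegion,
    known_frpo: Mapping[str, str] | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    max_mm35: int = 2,
    max_mm10: int = 2,
    spacer: tuple[int, int] = DEFAULT_SPACER,
    min_loop: int = 3,
    structure: BasePairStructure | None = None,
) -> FrpoCandidate:
    """Full per-region candidate evaluation (homology, consensus, structure).

    ``structure`` may carry an externally predicted structure (see
    ``structure_from_dot_bracket``); by default the internal base-pair
    maximization is used.
    """
    homology = None
    if known_frpo:
        homology = homology_scan([region], known_frpo, scheme)[region.gene_id]
    # classification allows up to the frpo_star mismatch budget per hexamer
    elements = scan_sigma70_elements(region.sequence, max(max_mm35, 2), max(max_mm10, 2), spacer)
    element = best_element(elements)
    hairpin = None
    if element is not None:
        if structure is None:
            structure = max_basepairs(region.sequence, min_loop)
        hairpin = hairpin_evidence(region.sequence, element, structure, scheme)
    tier = classify_candidate(homology, element, hairpin)
    return FrpoCandidate(
        region=region,
        tier=tier,
        homology=homology,
        element=element,
        hairpin=hairpin,
        structure_score=structure.n_pairs if structure is not None else 0,
        dot_bracket=structure.dot_bracket() if structure is not None else "",
    )


FRPO_TABLE_COLUMNS = (
    "contig_id", "gene_id", "region_start", "region_end", "strand", "tier",
    "homology_query", "homology_identity", "mm35", "mm10", "spacer",
    "up_at_fraction", "paired_fraction", "stem_support", "n_pairs", "dot_bracket",
)


def write_frpo_table(candidates: Sequence[FrpoCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FRPO_TABLE_COLUMNS) + "\n")
        for c in candidates:
            r = c.region
            hq = c.homology.query_id if c.homology else "."
            hid = f"{c.homology.percent_identity:.1f}" if c.homology else "."
            if c.element:
                mm35, mm10 = c.element.minus35_mismatches, c.element.minus10_mismatches
                sp, upf = c.element.spacer, f"{c.element.up_at_fraction:.2f}"
            else:
                mm35 = mm10 = sp = "."
                upf = "."
            pf = f"{c.hairpin.paired_fraction:.2f}" if c.hairpin else "."
            ss = c.hairpin.support_score if c.hairpin else "."
            fh.write(
                f"{r.contig_id}\t{r.gene_id}\t{r.start}\t{r.end}\t{r.strand}\t{c.tier}\t"
                f"{hq}\t{hid}\t{mm35}\t{mm10}\t{sp}\t{upf}\t{pf}\t{ss}\t"
                f"{c.structure_score}\t{c.dot_bracket}\n"
            )
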