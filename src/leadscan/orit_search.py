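"""Seeded short-word nucleotide local alignment.

A small built-in aligner in the spirit of ``blastn-short``: exact 5-mer seeds
on both strands, seeds clustered by diagonal, each cluster scored by an exact
banded local Gotoh dynamic program on a window around the seed diagonals.
Used to locate oriT queries and known Frpo/ssi promoters on contigs when an
external blast6 table is not supplied.  Scores are raw (match +1, mismatch
-3, gap of length L costs 5 + 2L); there is no e-value model — hits are kept
by raw score, and external blast6 input remains the high-fidelity path.

``local_align_oracle`` exposes the exact full-matrix optimum (same scoring)
for use as an independent test oracle on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seq import revcomp

NEG_INF = -(10**9)


@dataclass(frozen=True)
class ScoringScheme:
    """blastn-short-style scoring; a gap of length L costs gap_open + L*gap_extend."""

    match_reward: int = 1
    mismatch_penalty: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    word_size: int = 5
    x_drop: int = 10
    band: int = 20
    min_raw_score: int = 20

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.mismatch_penalty >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("penalties must be negative")


DEFAULT_SCHEME = ScoringScheme()


@dataclass(slots=True)
class AlignmentHit:
    """A local alignment of a query onto a subject (forward-strand coordinates)."""

    query_id: str
    subject_id: str
    sstart: int
    send: int
    strand: str
    raw_score: int
    percent_identity: float
    aligned_length: int


@dataclass(slots=True)
class LocalAlignment:
    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    n_identity: int
    n_columns: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.n_identity / self.n_columns if self.n_columns else 0.0


def build_word_index(subject: str, word_size: int = 5) -> dict[str, list[tuple[int, str]]]:
    """Index every exact ``word_size``-mer of the subject on both strands.

    The value list holds ``(forward_start, strand)``: a ``-`` entry at
    position p means the minus-strand read of subject[p:p+w] equals the word.
    Words containing N are skipped.
    """
    index: dict[str, list[tuple[int, str]]] = {}
    subject = subject.upper()
    for i in range(len(subject) - word_size + 1):
        w = subject[i : i + word_size]
        if "N" in w:
            continue
        index.setdefault(w, []).append((i, "+"))
        index.setdefault(revcomp(w), []).append((i, "-"))
    return index


def _encode(seq: str) -> np.ndarray:
    # A,C,G,T -> 0..3; anything else (N) -> 4, which never matches
    table = np.full(256, 4, dtype=np.int8)
    for i, c in enumerate("ACGT"):
        table[ord(c)] = i
        table[ord(c.lower())] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _gotoh_matrices(a: str, b: str, scheme: ScoringScheme):
    """Exact local Gotoh DP filled along anti-diagonals (vectorized).

    Returns (H, E, F, sub) int32 matrices of shape (len(a)+1, len(b)+1).
    """
    n, m = len(a), len(b)
    ea, eb = _encode(a), _encode(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)  # gap consuming b
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)  # gap consuming a
    go = scheme.gap_open + scheme.gap_extend
    ge = scheme.gap_extend
    for d in range(2, n + m + 1):
        lo, hi = max(1, d - m), min(n, d - 1)
        if lo > hi:
            continue
        i = np.arange(lo, hi + 1)
        j = d - i
        match = (ea[i - 1] == eb[j - 1]) & (ea[i - 1] != 4)
        sub = np.where(match, scheme.match_reward, scheme.mismatch_penalty).astype(np.int32)
        E[i, j] = np.maximum(H[i, j - 1] + go, E[i, j - 1] + ge)
        F[i, j] = np.maximum(H[i - 1, j] + go, F[i - 1, j] + ge)
        H[i, j] = np.maximum.reduce(
            [np.zeros_like(i, dtype=np.int32), H[i - 1, j - 1] + sub, E[i, j], F[i, j]]
        )
    return H, E, F


def _traceback(a: str, b: str, H, E, F, scheme: ScoringScheme) -> LocalAlignment:
    flat = int(np.argmax(H))
    i, j = divmod(flat, H.shape[1])
    score = int(H[i, j])
    a_end, b_end = i, j
    n_ident = n_cols = 0
    go = scheme.gap_open + scheme.gap_extend
    ge = scheme.gap_extend
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            match = a[i - 1].upper() == b[j - 1].upper() and a[i - 1].upper() in "ACGT"
            sub = scheme.match_reward if match else scheme.mismatch_penalty
            if h == H[i - 1, j - 1] + sub:
                n_cols += 1
                n_ident += int(match)
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            n_cols += 1
            if E[i, j] == H[i, j - 1] + go:
                j -= 1
                state = "H"
            else:
                j -= 1
        else:  # F
            n_cols += 1
            if F[i, j] == H[i - 1, j] + go:
                i -= 1
                state = "H"
            else:
                i -= 1
    return LocalAlignment(score, i, a_end, j, b_end, n_ident, n_cols)


def local_align(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> LocalAlignment:
    """Optimal local alignment (score and traceback) of a vs b."""
    if not a or not b:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0)
    H, E, F = _gotoh_matrices(a, b, scheme)
    return _traceback(a, b, H, E, F, scheme)


MAX_ORACLE_CELLS = 10**6


def local_align_oracle(
    a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> LocalAlignment:
    """Exact optimum by full dynamic programming (refuses |a|*|b| > 1e6)."""
    if len(a) * len(b) > MAX_ORACLE_CELLS:
        raise ValueError(f"oracle size cap exceeded: {len(a)}*{len(b)} > {MAX_ORACLE_CELLS}")
    return local_align(a, b, scheme)


def _cluster_diagonals(diags: list[int], band: int) -> list[tuple[int, int]]:
    """Group sorted seed diagonals into runs separated by more than band."""
    groups = []
    diags = sorted(set(diags))
    start = prev = diags[0]
    for d in diags[1:]:
        if d - prev > band:
            groups.append((start, prev))
            start = d
        prev = d
    groups.append((start, prev))
    return groups


def seed_and_extend(
    query: str,
    subject: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_id: str = "query",
    subject_id: str = "subject",
    index: dict[str, list[tuple[int, str]]] | None = None,
) -> list[AlignmentHit]:
    """Word seeding + banded exact extension on both strands.

    Seeds are grouped by diagonal; each group is rescored with the exact
    local DP restricted to a subject window spanning the group's diagonals
    plus ``scheme.band`` margin.  Overlapping hits are merged keeping the
    maximum-score one; hits with raw score below ``scheme.min_raw_score``
    are dropped.  Coordinates are always on the subject's forward strand.
    """
    if not query or not subject:
        return []
    w = scheme.word_size
    if index is None:
        index = build_word_index(subject, w)
    subject_u = subject.upper()

    hits: list[AlignmentHit] = []
    for strand in ("+", "-"):
        q = query.upper() if strand == "+" else revcomp(query.upper())
        diags: list[int] = []
        for qpos in range(len(q) - w + 1):
            word = q[qpos : qpos + w]
            if "N" in word:
                continue
            for spos, s in index.get(word, ()):
                if s == "+":
                    diags.append(spos - qpos)
        if not diags:
            continue
        windows = []
        for dlo, dhi in _cluster_diagonals(diags, scheme.band):
            lo = max(0, dlo - scheme.band)
            hi = min(len(subject_u), dhi + len(q) + scheme.band)
            windows.append((lo, hi))
        # merge overlapping windows to avoid duplicate work
        windows.sort()
        merged = [windows[0]]
        for lo, hi in windows[1:]:
            if lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        for lo, hi in merged:
            aln = local_align(q, subject_u[lo:hi], scheme)
            if aln.score < scheme.min_raw_score:
                continue
            hits.append(
                AlignmentHit(
                    query_id=query_id,
                    subject_id=subject_id,
                    sstart=lo + aln.b_start,
                    send=lo + aln.b_end,
                    strand=strand,
                    raw_score=aln.score,
                    percent_identity=aln.percent_identity,
                    aligned_length=aln.n_columns,
                )
            )

    # keep max-score hit among overlapping subject intervals
    hits.sort(key=lambda h: (-h.raw_score, h.sstart, h.strand))
    kept: list[AlignmentHit] = []
    for h in hits:
        if any(h.sstart < k.send and k.sstart < h.send for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: h.sstart)
    return kept


def hits_as_homology(hits: Sequence[AlignmentHit]):
    """Convert AlignmentHits to io_formats.HomologyHit records (raw score in bit_score)."""
    from .io_formats import HomologyHit

    return [
        HomologyHit(
            query_id=h.query_id,
            subject_id=h.subject_id,
            sstart=h.sstart,
            send=h.send,
            strand=h.strand,
            percent_identity=h.percent_identity,
            bit_score=float(h.raw_score),
            e_value=0.0,
        )
        for h in hits
    ]
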