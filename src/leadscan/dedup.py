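"""Redundancy removal by pairwise shared-ORF fraction.

Contigs are compared through an externally produced ORF cluster membership
(CD-HIT / MMseqs2 style): the shared fraction of a pair is the multiset
intersection of their cluster ids divided by the smaller contig's ORF count,
so a plasmid fully contained in a larger one scores 1.0.  Pairs sharing
strictly more than the threshold (default 0.9) are collapsed, keeping the
contig with more ORFs (ties broken by contig id), which makes the result
deterministic and independent of input order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence


class EmptyContigError(ValueError):
    """Shared-ORF fraction is undefined for a contig with no genes."""


@dataclass(slots=True)
class DedupResult:
    representatives: list[str]
    removed: list[tuple[str, str, float]]  # (removed_id, kept_id, fraction)


def read_membership(path: str | Path) -> dict[str, str]:
    """Read a two-column ``gene_id  cluster_id`` TSV (header optional)."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "gene_id":
            continue
        if len(parts) != 2:
            raise ValueError(f"membership line has {len(parts)} columns: {line!r}")
        mapping[parts[0]] = parts[1]
    return mapping


def write_membership(membership: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcluster_id\n")
        for gid in sorted(membership):
            fh.write(f"{gid}\t{membership[gid]}\n")


def _cluster_counter(gene_ids: Sequence[str], membership: Mapping[str, str]) -> Counter:
    # unmapped genes fall back to singleton clusters keyed by their own id
    return Counter(membership.get(g, f"__singleton__{g}") for g in gene_ids)


def shared_orf_fraction(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    membership: Mapping[str, str],
    use_multiset: bool = True,
) -> float:
    """Fraction of shared ORF clusters relative to the smaller contig."""
    if not genes_a or not genes_b:
        raise EmptyContigError("shared_orf_fraction undefined for an empty contig")
    ca, cb = _cluster_counter(genes_a, membership), _cluster_counter(genes_b, membership)
    if not use_multiset:
        ca, cb = Counter(set(ca)), Counter(set(cb))
    shared = sum((ca & cb).values())
    denom = min(sum(ca.values()), sum(cb.values()))
    return shared / denom


def deduplicate(
    contigs: Mapping[str, Sequence[str]],
    membership: Mapping[str, str],
    threshold: float = 0.9,
    use_multiset: bool = True,
) -> DedupResult:
    """Greedy keep-largest-first deduplication.

    A contig is removed when it shares strictly more than ``threshold`` of
    its ORF clusters with an already-kept contig (a pair at exactly the
    threshold is retained).  Input order does not affect the result.
    """
    order = sorted(contigs, key=lambda c: (-len(contigs[c]), c))
    kept: list[str] = []
    kept_counters: list[Counter] = []
    removed: list[tuple[str, str, float]] = []
    for cid in order:
        if not contigs[cid]:
            raise EmptyContigError(f"contig {cid} has no genes")
        counter = _cluster_counter(contigs[cid], membership)
        if not use_multiset:
            counter = Counter(set(counter))
        n = sum(counter.values())
        best_frac, best_partner = -1.0, None
        for kid, kc in zip(kept, kept_counters):
            shared = sum((counter & kc).values())
            frac = shared / min(n, sum(kc.values()))
            if frac > best_frac:
                best_frac, best_partner = frac, kid
        if best_partner is not None and best_frac > threshold:
            removed.append((cid, best_partner, best_frac))
        else:
            kept.append(cid)
            kept_counters.append(counter)
    return DedupResult(representatives=kept, removed=removed)


def write_dedup_table(result: DedupResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tstatus\tkept_partner\tshared_fraction\n")
        for cid in result.representatives:
            fh.write(f"{cid}\trepresentative\t.\t.\n")
        for cid, kid, frac in result.removed:
            fh.write(f"{cid}\tremoved\t{kid}\t{frac:.4f}\n")
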