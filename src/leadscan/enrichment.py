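"""Positional and gene-family enrichment statistics.

The central test asks, for each ORF position relative to the oriT, whether
the count of a functional category at that position is higher than expected
from the category's overall prevalence.  Formally the 2x2 table
[position vs all other positions] x [category vs not] is evaluated with a
one-sided (upper tail) Fisher exact test, i.e. the hypergeometric tail
P(X >= k) with X ~ Hypergeom(N, K, n) where N and K are the grand totals
and n the ORF count at the position.  P-values are corrected per run with
the Benjamini-Hochberg step-up at alpha (default 0.001) and only positions
with at least ``min_orfs`` (default 50) ORFs are tested.

Gene families are tested the same way, comparing each family's occurrences
within the first 28 leading positions (indices 0-27) against the rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .geometry import ContigGeometry
from .io_formats import ANTI_DEFENCE_CATEGORIES

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.001
DEFAULT_MIN_ORFS = 50
DEFAULT_LEADING_RANGE = (0, 27)

#: pseudo-category pooling the three anti-defence classes
COMBINED = "anti_defence"


def tally_positions(
    geometries: Iterable[ContigGeometry],
    categories: Mapping[str, str],
) -> pd.DataFrame:
    """Count ORFs (total and per category) at each relative position.

    Returns a DataFrame indexed by position with ``n_total``, one ``n_<cat>``
    column per observed category, and ``n_anti_defence`` pooling
    anti-CRISPR, anti-restriction and SOS-inhibitor counts.
    """
    totals: dict[int, int] = {}
    per_cat: dict[str, dict[int, int]] = {}
    for geo in geometries:
        for gid, pos in geo.relative_position.items():
            totals[pos] = totals.get(pos, 0) + 1
            cat = categories.get(gid, "uncharacterized")
            per_cat.setdefault(cat, {})[pos] = per_cat.setdefault(cat, {}).get(pos, 0) + 1
    positions = sorted(totals)
    data: dict[str, list[int]] = {"n_total": [totals[p] for p in positions]}
    for cat in sorted(per_cat):
        data[f"n_{cat}"] = [per_cat[cat].get(p, 0) for p in positions]
    df = pd.DataFrame(data, index=pd.Index(positions, name="position"))
    anti = np.zeros(len(df), dtype=int)
    for cat in ANTI_DEFENCE_CATEGORIES:
        col = f"n_{cat}"
        if col in df:
            anti += df[col].to_numpy()
    df[f"n_{COMBINED}"] = anti
    return df


def windowed_frequency(
    table: pd.DataFrame, window: int = 5, category: str = COMBINED
) -> pd.Series:
    """Category frequency smoothed over a centered ``window``-ORF window.

    f_w(p) = sum of category counts over the window / sum of totals over the
    window, with the window truncated at the edges of the index range.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    col = f"n_{category}"
    if col not in table:
        raise KeyError(f"no column {col} in table")
    full = table.reindex(range(table.index.min(), table.index.max() + 1), fill_value=0)
    num = full[col].rolling(window, center=True, min_periods=1).sum()
    den = full["n_total"].rolling(window, center=True, min_periods=1).sum()
    fw = (num / den.replace(0, np.nan)).fillna(0.0)
    fw.name = f"f_w_{category}"
    return fw.loc[table.index]


def fisher_one_sided(k, K, n, N):
    """Upper-tail hypergeometric p-value P(X >= k), X ~ Hypergeom(N, K, n).

    ``k`` category ORFs out of ``n`` at the position, against grand totals
    ``K`` of ``N``.  Accepts scalars or equally-shaped arrays.
    """
    k = np.asarray(k)
    K = np.asarray(K)
    n = np.asarray(n)
    N = np.asarray(N)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("need 0 <= k <= n")
    if np.any(K < 0) or np.any(K > N):
        raise ValueError("need 0 <= K <= N")
    if np.any(n > N):
        raise ValueError("need n <= N")
    if np.any(k > K) or np.any((n - k) > (N - K)):
        raise ValueError("cell counts exceed margins")
    p = hypergeom.sf(k - 1, N, K, n)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def bh_fdr(p_values: Sequence[float], alpha: float = DEFAULT_ALPHA):
    """Benjamini-Hochberg step-up: returns (q_values, reject_flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    # statsmodels rejects via the step-up rank rule; align the flag with q <= alpha
    return q, q <= alpha


def test_position_enrichment(
    table: pd.DataFrame,
    min_orfs: int = DEFAULT_MIN_ORFS,
    alpha: float = DEFAULT_ALPHA,
    categories: Sequence[str] = (COMBINED,) + tuple(ANTI_DEFENCE_CATEGORIES),
) -> pd.DataFrame:
    """Per-position one-sided Fisher tests with BH-FDR, per category.

    Positions with fewer than ``min_orfs`` ORFs are not tested (their p and
    q are NaN and they can never be flagged).  Each tested position is
    compared against the pooled counts of all positions.
    """
    out = table.copy()
    tested_mask = out["n_total"] >= min_orfs
    if not tested_mask.any():
        log.warning("no positions with at least %d ORFs; nothing tested", min_orfs)
    N = int(out["n_total"].sum())
    for cat in categories:
        col = f"n_{cat}"
        if col not in out:
            out[col] = 0
        K = int(out[col].sum())
        p_col = np.full(len(out), np.nan)
        q_col = np.full(len(out), np.nan)
        sig_col = np.zeros(len(out), dtype=bool)
        idx = np.flatnonzero(tested_mask.to_numpy())
        if idx.size and N > 0:
            k = out[col].to_numpy()[idx]
            n = out["n_total"].to_numpy()[idx]
            p = fisher_one_sided(k, K, n, N)
            p = np.atleast_1d(p)
            q, rej = bh_fdr(p, alpha)
            p_col[idx] = p
            q_col[idx] = q
            sig_col[idx] = rej
        out[f"p_{cat}"] = p_col
        out[f"q_{cat}"] = q_col
        out[f"sig_{cat}"] = sig_col
    out[f"f_w_{COMBINED}"] = windowed_frequency(table, category=COMBINED)
    return out


@dataclass(slots=True)
class FamilyEnrichmentResult:
    family_id: str
    size: int
    leading_count: int
    elsewhere_count: int
    p: float
    q: float = float("nan")
    enriched: bool = False
    majority_orientation: str = "tie"
    majority_annotation: str = "uncharacterized"


def family_orientation(flags: Sequence[bool]) -> str:
    """Majority vote of T-strand expressibility; exact ties -> 'tie'."""
    if not flags:
        raise ValueError("family has no members with geometry")
    yes = sum(flags)
    no = len(flags) - yes
    if yes > no:
        return "t_strand"
    if no > yes:
        return "opposite"
    return "tie"


def family_majority_annotation(annotations: Sequence[str]) -> str:
    """Modal annotation; ties broken lexicographically; empty -> uncharacterized."""
    labels = [a for a in annotations if a]
    if not labels:
        return "uncharacterized"
    counts: dict[str, int] = {}
    for a in labels:
        counts[a] = counts.get(a, 0) + 1
    top = max(counts.values())
    return min(label for label, c in counts.items() if c == top)


def test_family_enrichment(
    families: Mapping[str, str],
    geometries: Iterable[ContigGeometry],
    annotations: Mapping[str, str] | None = None,
    leading_range: tuple[int, int] = DEFAULT_LEADING_RANGE,
    min_size: int = 5,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Test each gene family for enrichment within the leading range.

    ``families`` maps gene_id -> family_id; only families with more than
    ``min_size`` occurrences on the analysed contigs are tested.  The 2x2
    compares family members inside positions ``leading_range`` vs elsewhere
    against total ORF counts in the same ranges, pooled over contigs.
    """
    lo, hi = leading_range
    geometries = list(geometries)
    total_lead = total_all = 0
    fam_lead: dict[str, int] = {}
    fam_all: dict[str, int] = {}
    fam_flags: dict[str, list[bool]] = {}
    for geo in geometries:
        for gid, pos in geo.relative_position.items():
            in_lead = lo <= pos <= hi
            total_all += 1
            total_lead += int(in_lead)
            fam = families.get(gid)
            if fam is None:
                continue
            fam_all[fam] = fam_all.get(fam, 0) + 1
            if in_lead:
                fam_lead[fam] = fam_lead.get(fam, 0) + 1
            fam_flags.setdefault(fam, []).append(geo.t_strand_expressible[gid])

    fam_annots: dict[str, list[str]] = {}
    if annotations:
        for gid, fam in families.items():
            if fam in fam_all and gid in annotations:
                fam_annots.setdefault(fam, []).append(annotations[gid])

    results: list[FamilyEnrichmentResult] = []
    for fam in sorted(fam_all):
        size = fam_all[fam]
        if size <= min_size:
            continue
        k = fam_lead.get(fam, 0)
        p = 1.0 if k == 0 else fisher_one_sided(k, total_lead, size, total_all)
        results.append(
            FamilyEnrichmentResult(
                family_id=fam,
                size=size,
                leading_count=k,
                elsewhere_count=size - k,
                p=float(p),
                majority_orientation=family_orientation(fam_flags[fam]),
                majority_annotation=family_majority_annotation(fam_annots.get(fam, [])),
            )
        )
    if not results:
        log.warning("no families larger than min_size=%d to test", min_size)
        return pd.DataFrame(
            columns=[
                "family_id", "size", "leading_count", "elsewhere_count",
                "p", "q", "enriched", "majority_orientation", "majority_annotation",
            ]
        ).set_index("family_id")
    q, rej = bh_fdr([r.p for r in results], alpha)
    for r, qi, ri in zip(results, q, rej):
        r.q, r.enriched = float(qi), bool(ri)
    import dataclasses

    df = pd.DataFrame([dataclasses.asdict(r) for r in results]).set_index("family_id")
    return df
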