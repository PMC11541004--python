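# Methods

This note documents the models, conventions and numerical choices behind
`leadscan`, in the order the pipeline applies them.

## Contig orientation around the oriT

A contig is analysable when it carries a relaxase/TraM gene and an oriT
hit.  Quality filters (applied in this order, with per-contig rejection
reasons logged):

* `no_relaxase` / `no_orit` — either anchor missing;
* `too_many_relaxases` — more than two relaxase/TraM hits (ambiguous
  relaxosome);
* `too_far` — more than 3,500 bp between the relaxase gene and the oriT
  (default `max_orit_distance`, measured as the gap between the two
  intervals, 0 when they overlap);
* `orit_inside_relaxase` — the oriT wholly contained in the relaxase gene
  (partial overlap is retained);
* `edge_placement` — the relaxase is the first or last annotated gene, or
  the oriT midpoint falls outside the span of gene midpoints.  In either
  case the relative order of oriT and relaxase on the replicon cannot be
  established from the fragment.

When a contig has several oriT hits the best-scoring one is used (ties:
lowest e-value, leftmost, lexicographic query id).  With two admissible
relaxase hits the gene nearer the oriT anchors the geometry.

The leading side is the side of the oriT away from the relaxase, because
the relaxase enters the recipient last.  The exact nic position inside the
oriT is unknown, so the oriT midpoint serves as the anchor; only the
relative order of ORFs matters for position indices.  Each gene is
assigned to a side by its midpoint (a midpoint exactly on the anchor
counts as leading) and indexed outward: 0, 1, 2, … on the leading side,
−1, −2, … on the lagging side.  The whole construction is invariant under
reverse-complementing the contig (x → L − x with strand flips), which the
test suite checks exhaustively on simulated fixtures.

**T-strand expressibility.**  The transferred strand's 5′ end is at the
nic, so transcription that can run off the entering single strand points
*against* the leading direction.  The default convention
(`toward_oriT`) therefore flags a gene as T-strand expressible iff its
transcription direction opposes the leading direction; the opposite
convention is available in the configuration because the operational
strand test is a modelling choice, not an observable.

Contigs are treated as linear assembly fragments.  Indices do not wrap;
circular topology support would change only the index assignment.

## Deduplication

Redundant contigs are collapsed using an external ORF clustering
(CD-HIT/MMseqs2-style membership table).  The shared fraction of a pair is
the *multiset* intersection of cluster ids divided by the smaller contig's
ORF count: multiset, because plasmids carry genuine gene duplicates;
smaller-denominator, so that a sub-plasmid contained in a larger one
scores 1.0 and is removed.  Pairs sharing strictly more than 0.9 are
collapsed keeping the contig with more ORFs (ties: lexicographically
smaller id).  Iterating contigs sorted by (ORF count desc, id) makes the
result deterministic and independent of input order; exactly-0.9 pairs
are both kept.  Set-based counting is available as an option.

## Enrichment statistics

Per-position testing uses the one-sided Fisher exact test: with k
category ORFs among the n ORFs at a position, and K of N overall, the
p-value is the upper hypergeometric tail P(X ≥ k), X ~ Hypergeom(N, K, n),
computed via `scipy.stats.hypergeom.sf`.  Note that "position versus the
pooled complement" and "position versus the grand totals" describe the
same hypergeometric once the 2×2 margins are formed, so no background
switch is needed.  Only positions with at least 50 ORFs are tested
(below that the test has essentially no power and the index tail is
dominated by a handful of long contigs).  P-values are corrected per run
with Benjamini–Hochberg (step-up) at α = 0.001; the package reports
monotone q-values and rejects at q ≤ α.  The combined anti-defence
category pools anti-CRISPR, anti-restriction and SOS-inhibitor counts;
each category is also tested separately.

Family testing compares, for each gene family (cluster), its occurrences
at leading positions 0–27 versus elsewhere against the total ORF counts
in the same ranges, pooled over the analysed contigs, with BH-FDR across
families.  Families at or below `family_min_size` (default 5; the real
corpus analogue would use hundreds) are skipped.  A family's orientation
is the majority vote of its members' T-strand flags ("tie" on exact
ties) and its annotation the modal member label (ties resolved
lexicographically; no labels → "uncharacterized").

One indexing wrinkle: leading ORFs are described in the field both as
"positions 1–28" and with a 0-based axis where 0 is the first leading
ORF.  `leadscan` uses the 0-based convention throughout, so "the first 28
leading ORFs" are internal indices 0–27 (`leading_range = (0, 27)`).

The five-ORF frequency window is centered and truncated at the ends of
the index range (denominator sums only existing positions).  The
≥500-sequences filter applied when displaying position tables is a
report-layer filter only; statistics are always computed on the full
table.  MOB-type exclusion (`mob_exclude`) drops whole contigs from the
enrichment stage; MOB labels are consumed as metadata and never inferred.

## Anti-defence islands

Islands are formalized as maximal runs of island-qualifying genes
(anti-CRISPR, anti-restriction, SOS inhibitor, MTase, SSB,
toxin–antitoxin) on the leading side: a run must start within positions
0–27, tolerates at most `max_gap` = 2 consecutive non-qualifying genes,
terminates immediately before a umu-like gene (recorded as boundary
`umu_like_operon`; the oriT is always the near boundary) and must contain
at least `min_members` = 3 qualifying genes.  Runs may extend past
position 27; members beyond it are flagged.  The run/gap formalization is
this package's operational definition — real islands are recognized
qualitatively — so the unit tests pin the implementation against an
independent linear re-derivation of the rules rather than against
biology.  Transposases are deliberately non-qualifying: a transposase
inside a run consumes gap budget, which reproduces the observed pattern
of adjacent islands separated by a transposase with umu-like operons
flanking each.

## Frpo/ssi promoter detection

Upstream regulatory regions are the strand-aware intergenic spans between
a leading-region gene's start and the previous feature (neighbouring gene
or the oriT), kept when 50–350 bp long and reverse-complemented for
minus-strand genes so scanning always runs 5′→3′ in coding orientation.

Three lines of evidence per region:

1. **Homology** to known Frpo/ssi queries via the package aligner
   (word size 5; raw score ≥ 20).  Any hit ⇒ tier `frpo`.
2. **σ70 consensus**: all −35/−10 hexamer pairs (TTGACA / TATAAT) with at
   most 2 mismatches per hexamer and a 15–19 nt spacer; the AT fraction
   of the 20 nt upstream of the −35 (the UP element) is reported, with
   ≥ 0.75 flagged as AT-rich (reported, not required for a tier).
3. **Structure**: deterministic base-pair maximization (Nussinov-style
   DP, Watson–Crick + GT wobble pairs, minimum hairpin loop 3, traceback
   preferring the smallest-i/largest-j pairing) replaces thermodynamic
   folding; it is exactly testable by enumeration and sufficient to score
   stem coverage.  The paired fraction of the 12 element nucleotides in
   the optimal structure is reported and must reach 0.5.  Because
   maximum-pairing structures of *any* ~100–350 nt sequence pair most
   positions (empirically > 0.65 of bases even for random DNA), the
   paired fraction alone cannot distinguish a real stem from incidental
   pairing.  Classification therefore additionally requires **duplex
   support**: a local alignment of the −35…spacer…−10 block against the
   reverse complement of the rest of the region scoring ≥ 12, i.e. an
   actual complementary partner block such as those seen in real
   Frpo secondary structures.  A configuration hook accepts an external
   folder's dot-bracket string in place of the internal structure.

Tiers: `frpo` (homology), `frpo_prime` (≤ 2 total hexamer mismatches +
stem evidence), `frpo_star` (≤ 4 total mismatches + stem evidence),
`none`.  The mismatch budgets, spacer bounds and support threshold are
operational definitions exposed in the configuration; with them, ≥ 90 %
of simulator-planted elements are recovered at tier ≥ frpo_prime while
dinucleotide-shuffled controls stay below 10 % at tier ≥ frpo_star
(seeded tests).

## Built-in aligner

The aligner mimics a short-query nucleotide search: exact 5-mer seeds on
both strands, seeds clustered by diagonal (clusters merged within a
20-diagonal band), each cluster rescored by an exact local Gotoh DP on a
window spanning the cluster ± band.  Scoring is match +1, mismatch −3, a
gap of length L costs 5 + 2L.  There is no e-value model: hits are kept
at raw score ≥ 20 (≈ a 20 nt exact match), which is deterministic and
testable; statistical-significance calibration is out of scope and an
external blast6 table remains the high-fidelity input path.  Because the
extension is an exact DP on the seeded window, the heuristic recovers the
full Smith–Waterman optimum whenever the optimal alignment lies inside a
seeded window — the admissibility property (≥ 0.9 × optimum at ≥ 90 %
identity) holds with large margin in the seeded tests.  The DP is filled
along anti-diagonals with numpy, so the full-matrix oracle
(`local_align_oracle`, capped at |a|·|b| ≤ 10⁶) is fast enough to run
inside the test suite and is additionally cross-checked against
Biopython's `PairwiseAligner` under the equivalent gap parameterization.

## Synthetic data

The simulator emits the exact dialects the readers consume (GFF3, FASTA,
blast6, tblout, membership TSV) plus a truth JSON, deterministically from
a mandatory seed.  Each contig carries one relaxase adjacent (≤ 3,500 bp)
to one oriT copied (with 2 % mutation by default) from a bundled
*synthetic* stand-in query set — the real oriT databases are external and
are not shipped.  Default study conditions: 40–80 genes per contig,
anti-defence frequency 0.20 at leading positions 0–27 versus 0.01
elsewhere, anti-defence cargo always in the T-strand-expressible
orientation (`t_strand_prob = 1.0`), umu-like genes opposing the T-strand
with probability 0.9, MOB labels uniform over six types, and half of the
contigs mirrored so both leading directions are exercised.  Optional
features: exact or mutated duplicate contig groups (for dedup), explicit
islands terminated by a two-gene umu-like operon, and Frpo elements
planted in the intergenic region upstream of an expressible leading gene
(UP element, −35, 17 nt spacer, −10, 4 nt loop, perfect complementary
stem; mismatches injected per requested tier; `none` = dinucleotide
shuffle of a planted construct, preserving composition).

What the simulator does **not** emulate: real sequence composition
(intergenic background is i.i.d. uniform ACGT), phylogenetic structure,
MOB-type biology, gene length distributions, overlapping genes, assembly
artefacts, or homology between unrelated contigs beyond the planted
family clusters.  Passing tests therefore demonstrate the correctness of
the machinery and its statistical calibration under the stated generative
model, not performance on real assemblies.

## Problem sizes and numerical notes

The test suite exercises the exact Fisher implementation against a
brute-force binomial-coefficient tail summation for *every* margin
combination up to N = 200, the folding DP against exhaustive structure
enumeration up to length 14, and BH-FDR against the naive step-up on
1,000 random vectors.  Statistical calibration runs use 1,000 contigs for
planted-signal recovery and 20 × 2,000 contigs for null (type-I) control
— sizes at which the binomial fluctuations of the planted frequencies are
an order of magnitude smaller than the planted effect.  Hypergeometric
tails are computed in double precision (agreement with the exact
summation is ~1e-13); no log-space path is needed at these table sizes.

## Known limitations

* The oriT midpoint stands in for the nic site; positions of genes
  overlapping the oriT are resolved by a tie rule rather than biology.
* Relaxase/TraM detection, gene calling, ORF clustering and MOB typing
  are consumed as inputs, never computed.
* The promoter tiers are operational; in particular `frpo_star` is a
  low-certainty class by construction and the duplex-support threshold
  trades recall for a controlled false-positive rate on shuffled
  sequence.
* Base-pair maximization ignores thermodynamics; a G·U-rich stem scores
  as well as a GC stem.
* Linear contigs only; a circular flag would need wrap-around indices.
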