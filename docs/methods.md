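# Methods

## Coordinate and transcript conventions

All coordinates are 0-based half-open. Minus-strand alignments store
forward-strand query coordinates plus a strand flag; conversion happens
only at the alignment step itself (the reverse complement is aligned and
coordinates mapped back). Alignment transcripts use six symbols with
fixed consumption rules (`=`/`X`: 3 bases + 1 residue; `/`: 2 + 1;
`\`: 4 + 1; `D`: 3 + 0; `I`: 0 + 1), so a transcript fully determines
the bases and residues an alignment consumes; every row is audited
against its coordinates on read and write.

## Frame-shift-aware alignment

The aligner is a local (Smith-Waterman) dynamic programme over (query
base, subject residue) cells with three matrices (match, gap-in-query,
gap-in-subject) and two extra match transitions:

* consume 3 bases — ordinary codon column, substitution score
  `S(translate(codon), residue)`;
* consume 2 bases — frame decrease `/`: the codon is N-padded on the 5'
  side, hence translates to X; score `S(X, residue) − F`;
* consume 4 bases — frame increase `\`: the last 3 consumed bases are
  translated; score `S(aa, residue) − F`.

Choices and their rationale:

* **One penalty `F` per event** (default 15), not per base of shift: the
  penalty is a single configurable value in the tools this emulates.
* **Codon scoring at events** (N-pad the 2-base codon; translate the last
  3 of 4) is not specified anywhere authoritative; this convention gives
  every column a substitution score, makes the brute-force enumeration
  oracle well-defined, and makes correction arithmetic exact (2 + 1 = one
  codon, 4 + 2 = two codons).
* **Substitution scores**: BLOSUM62 with the X row/column forced to −1;
  affine gaps 11/1 — common translated-search defaults, configurable via
  `ScoringScheme`. Codons containing N translate to X.
* **Bit scores** use the gapped BLOSUM62 Karlin-Altschul constants
  (λ = 0.267, K = 0.041) and are reporting-only; culling and selection
  order use raw scores (with fixed constants the orderings coincide).
* **Determinism**: traceback prefers match > frame-shift > gap, and the
  smaller query consumption within the frame-shift pair; the maximum cell
  is the first in row-major order. Suboptimal hits come from repeated
  traceback with previously reported query intervals masked — far simpler
  than X-drop machinery and sufficient at desk scale.
* The kernel is JIT-compiled with numba (first call per process costs a
  few seconds of compilation); correctness is pinned by an independent
  pure-Python enumeration oracle over all monotone alignment paths with
  ≤ 2 events, which provably contains the optimum for subjects of ≤ 4
  residues at F = 15.

**Known behaviour, not a bug**: two indels within a couple of codons
merge. An insertion-deletion pair restores frame between them, and
bridging the short out-of-frame stretch as a few mismatches (≈ 5 points
each) is cheaper than a second F = 15 penalty; two same-type indels
collapse into one opposite-direction event. At a 1%/base indel rate
roughly a third of indels have a neighbour within ~20 bases, so detected
events undercount injected indels by ~25%. Frame restoration is
unaffected — the merged events still restore frame — but "events per kb"
should be read as a lower bound on the indel rate.

## Range-culling

Alignments of one query are processed in descending raw score (ties:
ascending query start, then subject id); A is culled iff an
already-retained B covers ≥ 50% of A's query interval and A scores below
90% of B. The witness must itself be retained (the unstated case); the
output is idempotent under re-culling.

## Correction

Selection is greedy by descending raw score (the natural reading of
"greedy"; ties as above), keeping an alignment iff its query interval
shares no position with a kept one — half-open, so abutting alignments
are compatible. Insertions land at the first (leftmost, forward-strand)
base of the shifted codon: the 2-base codon becomes N + 2 bases and the
4-base codon 4 + 2 bases, which makes the length law
(`out = in + #'/' + 2·#'\'`) and frame restoration exact on both strands.
Corrected records carry a strictly monotone original → corrected
coordinate map and the inserted positions, so correction is invertible
byte-exactly. Unaligned reads pass through unchanged by default
(`drop_unaligned=False`).

## LCA binning

A read's aligned bases are the union length of its alignment query
intervals. For each taxon, subtree coverage aggregates the intervals of
every alignment whose taxon lies in the subtree; the read is assigned to
the deepest taxon with coverage ≥ `coverage_percent` (51 by default,
inclusive ≥). Because the threshold exceeds 50%, qualifying taxa form a
single root chain and the deepest is unique up to exact ties, broken by
larger covered-base count then lexicographic id (how upstream tools break
such ties is unknown; this is a local decision). This is a minimal
re-implementation driven by three parameters — long-read LCA mode, the
51% threshold, aligned-base counts — and does not reproduce any
particular binning tool's full published algorithm. Shannon diversity is
computed with natural logarithms on genus-level bin counts.

## Assembly verification

* **Frame-shifts per kb**: per query, `1000 × events / union of aligned
  intervals`; cohort mean and sample standard deviation (n − 1).
* **Concordance κ**: mean of c₁ (mean best-hit-length / contig-length
  over bin contigs, 0 for contigs without hits), c₂ (mean identity of the
  hits as a fraction; 0 when there are no hits, so empty-overlap bins
  degrade to κ = 0 rather than erroring), c₃ (fraction of the long-read
  contig covered), c₄ (fraction of bin contigs with a hit). Identity is
  rescaled to [0,1] so all four components share a scale; per-contig
  ratios are clipped at 1. One best hit per contig-contig pair is the
  caller's contract.
* **Clone coverage**: a pair is a valid clone iff both mates hit the same
  contig, inward-facing forward-reverse, with outer span (rightmost end −
  leftmost start) strictly below `max_insert` = 800 ("distance" is read
  as the outer span; the strict inequality is a recorded choice). Valid
  clones increment coverage over their full span. Zero-coverage runs are
  reported as potential break-points; runs touching a contig end are
  flagged terminal, since clones cannot span ends.
* **Repeat rate**: positions inside non-trivial self-alignments of length
  ≥ 500 bp are masked, on both the query and the target interval of each
  hit (repeats are symmetric); rate = 100 × masked / length.
* **Pearson correlation** is scipy's sample coefficient, reported at 4
  decimal places.

## Synthetic data

Generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`. Reads carry iid per-base substitutions (1%)
and **single-base** indels (1%, split evenly between insertion and
deletion) — the dominant long-read frame-shift error mode; multi-base
indels are excluded so truth and recovery stay exact. Genes use uniform
codon usage with a fixed ATG start and no in-frame stops (composition
realism is irrelevant to the algorithms under test), and no quality
scores are modelled (the methods use none). Defaults (2 kb reads, ≥ 700
aa genes so a read fits inside one gene) match the scale at which frame
restoration is asserted: ≥ 95% of 200 corrected reads re-align with zero
events inside their corrected intervals.

The tiling-bin fixture emits constructed best hits (window coordinates
are known by construction) rather than running a nucleotide aligner; its
expected κ is computed analytically (c₁ = c₄ = related fraction, c₂ =
identity, c₃ = coverage fraction). The clone-pair generator samples spans
uniformly within each non-gap segment and additionally anchors one
boundary-flush clone at each segment end; without the anchors the exact
gap boundaries would be realised only with probability ≈ n/segment-length
per boundary, and the recovered break-point would jitter around the true
gap. No clone ever spans the gap.

What a green test does **not** establish: performance on real nanopore
error profiles (homopolymer-biased, bursty), on multi-gene reads with
intergenic sequence, or at reference-database scale — the aligner is
exact DP, not a seeded heuristic search, and is meant for desk-scale
validation and correction, not for searching NCBI-scale databases.

## Degenerate inputs and tie-breaks

Queries shorter than one codon return no alignment. Empty alignment sets:
correction passes reads through; `frameshift_stats` raises (rate
undefined); `concordance` of a hit-less bin returns κ = 0. Constant
vectors make `pearson` raise rather than return NaN. All-zero count
tables make `shannon_index` raise.
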