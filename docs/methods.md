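# Methods

## Site model

The binding preference of the Ci/Gli family is modelled as a
mono-nucleotide frequency matrix over {A,C,G,T}. Each matrix position is
summarised by a consensus index value,

    CIV(i) = (100 / ln A) · Σ_b f(i,b) · ln(A · f(i,b)),   A = 4,

the relative entropy to the uniform base distribution rescaled to
[0, 100]: exactly 0 when a position accepts any base equally and exactly
100 at strict single-base preference (0·ln 0 := 0). The published
definition gives only these two endpoint anchors; this package uses the
4-letter normalisation by default and exposes the gap-inclusive 5-letter
variant (`alphabet_size=5`) as a configuration switch. The scoring core
is the leftmost maximal contiguous run of positions with CIV above a
threshold (default 70); on an 11-position Ci-style matrix with nine
sharp leading positions this selects positions 1–9, and the run length
becomes the scan width.

The matrix similarity score of a core-width sequence is the
CIV-weighted frequency sum divided by the same sum for the consensus
(per-position argmax base, alphabetical tie-break, logged). MSS lies in
[0, 1], equals 1 exactly at the consensus, and is invariant to rescaling
all CIV weights — both properties are asserted as tests. Sequences
containing non-ACGT characters are rejected rather than imputed; the
scanner pre-filters N-containing windows.

## Vocabulary

Rather than rescoring every genomic window against the matrix, the
package enumerates the full thresholded vocabulary once: all 4^9
core-width k-mers with MSS ≥ `min_mss` (default 0.75) that also carry
concordant bases — C/C or G/G — at core positions 4 and 6, two positions
critical for Ci/Gli binding. Reverse complements of the sense set form
the antisense set and inherit the sense partner's MSS. Enumeration is
vectorised over base-4 k-mer indices and capped at width 12 (4^12
entries) to bound memory. Scanning then reduces to a rolling base-4
window index and two table lookups, which is what makes thousands of
background-genome scans affordable.

Exact-interval hits on both strands are merged into a single record
keeping the higher-MSS orientation, + on ties (a configuration of the
scanner's dedup contract; overlapping but non-identical intervals are
all kept). Sites in soft-masked (lowercase) sequence are found normally
and handled by the repeat filter downstream, never suppressed at scan
time.

## Background models and composition correction

Three per-chromosome randomizations are implemented:

* **random** — every non-N base redrawn uniformly; destroys the GC
  landscape.
* **shuffle3mer** — the sequence is cut into contiguous non-overlapping
  3-mers and the blocks are permuted; a trailing remainder of 1–2 bases
  stays in place (the simplest rule consistent with block parsing).
  Global composition is preserved, local composition is homogenized.
* **flip_gc_at** — each base is independently kept or complemented with
  probability 1/2. Since G↔C and A↔T, the GC identity of every single
  position — hence the GC fraction of every window of every width — is
  preserved exactly. This is the default, because the motif is GC-rich
  and a homogenizing background would overstate enrichment in GC-rich
  regions and understate it elsewhere.

Flipped chromosomes still carry fewer motif hits than the native
sequence (a matching GC skeleton only yields the motif when all ~9
coin-flips land right), which would inflate every enrichment ratio. The
correction: scan `n_raw` raw background replicates (default 1000;
smaller values are used in tests and the acceptance script since the
correction step makes the downstream statistic insensitive to pool
depth), pool every hit's position per k-mer with duplicates retained,
then rebuild `n_replicates` (default 100) background site maps by
drawing, per k-mer, exactly the native chromosome's site count from that
k-mer's pool — uniformly over pool entries, without replacement within a
replicate, with coordinate collisions rejected and redrawn. A k-mer
whose pool cannot supply enough distinct positions borrows from the pool
of its MSS class (MSS rounded to 0.01, logged); if that still fails the
run stops with advice to raise `n_raw`. Composition equality is exact by
construction and asserted exhaustively in the tests.

## Clustering coefficient and filter cascade

Candidate clusters are windows of 3–10 consecutive native sites whose
end-to-end span (outside ends of the flanking sites) is at most 1000 bp,
boundary inclusive. For each window,

    CC = observed sites / max(expected, floor),

where `expected` is the mean number of background sites fully contained
in the same interval across the replicates (full containment of the
9-bp site, symmetric with the outside-ends span definition) and
`floor = 1/n_replicates` keeps the ratio defined and monotone when no
background site ever lands in the window.

Filters, evaluated as a conjunction (the order CC → anchor MSS →
exon/repeat → site-fraction only affects flag readability): CC ≥ 4; at
least one member site with MSS ≥ 0.81; no member site overlapping an
exon or repeat interval by ≥ 1 bp; member sites covering at most 25% of
the span, with overlapping site bases counted once. Failed windows are
retained with per-filter flags in the verbose report so the cascade is
auditable.

Passing windows that share a member site are grouped (consecutive-site
windows share a member iff their index ranges overlap, so grouping is a
range merge) and each group is reported by its window with the most
sites, ties broken by higher average MSS, then leftmost start; all
candidate windows are also emitted, so the merge loses no information.
The final ranking is by average MSS descending (the enrichment ratio is
a filter, not a ranking tool), ties by site count then coordinate.

Annotation assigns each site or cluster its nearest transcript by
interval-hull distance (0 when overlapping; sign = genomic left/right;
gene-body rather than TSS distance, a documented config-able choice),
a feature label (exon / intron / upstream / downstream relative to
transcript strand), the nearest CTCF boundary distance, and a gene locus
using midpoint boundaries between neighbouring gene hulls (exact
midpoint goes left, logged). The cross-species filter keeps clusters
overlapping a pre-lifted cluster interval from a second assembly by
≥ 1 bp, sequence identity ignored; coordinate lifting itself is consumed
as input, not computed.

## Synthetic data

The `synthetic` module generates the study conditions end to end:
chromosomes drawn segment-by-segment with a prescribed GC fraction
(G/C and A/T equiprobable within their class), planted k-mers at fixed
offsets or expanded from cluster recipes (n sites spread evenly over a
span, k-mers drawn from a requested MSS band), and optional decoy
scrubbing that re-randomizes any unplanted vocabulary match (never
touching planted bases) until a scan recovers exactly the planted truth
— verified by brute-force string search. Toy matrices place weight
`sharpness` on a consensus base and split the rest evenly; sharpness
must exceed ≈0.91 for a position's CIV to clear the core threshold of
70, and the default test matrix uses 0.92, giving a 212-k-mer vocabulary
with MSS levels 1.0 / 0.892 / 0.784 at the 0.75 cutoff.

What the generator does not emulate: real repeat structure, isochore-
scale GC gradients, dinucleotide correlations, or evolutionary
divergence between species (the orthology filter needs only intervals).
Passing tests therefore demonstrate correctness of the statistics and
the cascade under controlled composition, not predictive performance on
real genomes.

## Problem sizes and numerical choices

Test fixtures default to 100 kb chromosomes; the suite uses 10–50 raw
background replicates and 20–100 corrected replicates, which the
composition correction renders equivalent to the full-depth setting for
the CC statistic. The planted-recovery experiment uses 100 seeded runs
of a 100 kb genome with one 5-site cluster (span ≤ 800 bp, member MSS
≥ 0.9) at `n_raw=50, n_replicates=20`. All generators are deterministic
given (seed, input); pipeline runs with equal seed and config reproduce
every output file byte-for-byte. Frequency rows must sum to 1 within
1e-6; degenerate inputs (all-zero matrix positions, empty FASTA records,
inverted intervals, windows shorter than the scan width) raise
immediately with the offending location named.

## Known limitations

* The enrichment ratio carries no p-value; CC ≥ 4 is a fixed operating
  point chosen to capture known enhancers, and calibration on a null
  genome is reported by the tests, not thresholded.
* The vocabulary treats the matrix as position-independent
  (mono-nucleotide); higher-order dependence is out of scope.
* Whole-genome memory use is linear in chromosome length (sequences are
  held in memory); the design targets fly-scale genomes, not mammalian
  assemblies.
* Reproducing the published genome-wide site and cluster tables requires
  the original proprietary matrix and reference genomes; with any other
  matrix the pipeline is exact but the specific counts (e.g. the
  vocabulary size) differ.
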