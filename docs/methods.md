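# Methods

This note records the models, estimators and numerical choices behind
`mitoforms`, what the simulator does and does not emulate, and the problem
sizes used by the test suite.

## The structural model

A mitochondrial genome is described by a set of **primary structural
units** — maximal unambiguous sequence segments, named with letter codes —
each with an integer copy number.  Units at copy number ≥ 2 are **large
repeats** ("hinges").  An **isoform** is a circular (optionally linear)
arrangement of oriented unit instances in which each unit appears exactly
copy-number times.  The genome *in vivo* is a mixture of isoforms at
frequencies summing to 1; recombination at a hinge exchanges the flanking
segments and interconverts isoforms, so hinge-adjacent junctions are shared
between isoforms while the *pairing* of entries and exits through a hinge
differs.

Circular arrangements are stored canonically: the lexicographically
minimal rotation over both the arrangement and its strand-flipped reversal,
with ties broken on "name+strand" tokens.  This is needed because any
linearization of a circularly permuted genome is arbitrary.

Built-in unit tables: *L. sativa* — 11 units totalling 314,646 bp, repeats
{M, N, R, T} (N rides with M as the MN repeat); *L. saligna* — 10 units
totalling 323,254 bp, repeats {M, R, T}.  With the repeats at two copies
the full genomes are 363,324 bp and 368,269 bp.  The default isoform
arrangements are **constructed models**: they satisfy the published order
constraints (the M-N-K-M-N-W-Z run; R and T each joined to both P and U;
the saligna M-S-M, M-V and V-Z junctions) but the complete deposited unit
orders are not public, so the defaults should not be read as transcriptions
of the archived sequences.  For saligna the complementary half of the eight
repeat-flanking blocks cannot lie on one circle (the pairing Z-R-U, L-R-P,
P-T-L, K-T-Q closes a 4-cycle through L-R-P-T), so the default mixture is
one full circle plus its two recombination products — consistent with that
genome resisting a single stoichiometrically symmetric model.

DNA contour measurements convert at 3.0 kb/μm.  The canonical B-form value
(~2.94 kb/μm) was rejected in favor of the ratio that the source
measurements themselves use (10 μm ≈ 30 kb; 363 kb ≈ 121 μm).

## Simulator

`simulate` draws every stage from named substreams of a single seed
(genome, long reads, each mate-pair library, Hi-C), so outputs are
byte-identical given a seed and independently reproducible per stage.

* Unit sequences are i.i.d. uniform bases unless supplied.  Dispersed
  repeats are planted by copying (optionally reverse-complementing) a
  subsequence between unit locations, giving exact duplicates.
* Long reads: molecule chosen with probability ∝ frequency × length;
  lognormal lengths (default mean 15 kb, σ = 0.35 of the underlying
  Normal — the source data's length distribution is not published, so this
  is a default, not a claim); circular molecules sampled with wrap-around
  via sequence doubling; per-base substitution/insertion/deletion errors at
  1% each by default.  Real CLR error is higher; the default is kept low so
  the built-in aligner's seed density stays comfortable, and it is an
  explicit knob.  Reads are drawn until total bases reach coverage × mean
  molecule length.
* Mate pairs: outer distance Normal(mean, sd) truncated above twice the
  read length (100 nt reads, FR layout), substitution errors only at 0.1%.
  Chimeras and duplicates are not simulated.
* Hi-C: two GATC-bounded loci on one molecule, separation from a power law
  (default exponent 1.5, minimum 1 kb), emitted as a single chimeric read
  containing the GATC-GATC ligation scar at a recorded offset; flanks are
  error-free by construction so the scar is exact.
* Crossover at a planted direct repeat converts a circle into its two
  subcircle products.  At crossover fraction *f* the molecule pool is
  {major: 1−f, productA: f, productB: f}, renormalized — each event yields
  one copy of each product.

What passing tests on this simulator do **not** show: robustness to real
CLR/ONT error profiles and chimeric reads, to biased coverage, to nuclear
or plastid paralogy beyond the decoy filter, or to unit tables that are
themselves wrong.  The simulator's role is to verify the inference logic
under known truth, not to emulate instrument physics.

## Alignment engine

All long-read alignment uses one seeded chained aligner: exact 15-mers of
the queries (both strands) in a sorted array; read k-mers sampled at a
stride (5 for tiling mapping, 10 for coverage counting) looked up
vectorized; matches bucketed per (query, strand) and split at diagonal
jumps > 120 bp; each cluster verified with an infix edit-distance alignment
(edlib) over a padded window.  Two verification levels: full path
reconstruction with end-mismatch trimming (used where CIGARs are needed),
or distance-only (several-fold faster; identity estimated as
1 − d/columns).  Clusters whose exact-seed footprint already covers the
required span at density ≥ 0.3 skip verification entirely, with identity
estimated from the seed rate (seed survival ≈ identity^k); clusters whose
query/read overlap bound cannot reach the minimum length are skipped
without verification.  The published workflow used BLAST-N with relaxed
gap parameters for this step; the built-in aligner replaces it to avoid an
external binary, and an adapter ingests outfmt-6-style tables from any
external mapper.

"Uninterrupted" alignment (junction support) is operationalized as a
single chained alignment with no internal indel run > 50 bp; the 1.8 kb
support threshold is the only magic number and is scaled down
(0.9 × fragment length) for flank-limited junction fragments.

Unit paths collapse runs of consecutive same-unit fragment hits with
monotone indices ('+' increasing, '−' decreasing).  Runs shorter than
2 fragments are discarded unless the unit is too short to yield more
(guarding against single stray 2 kb hits creating phantom units), and a
run split by a discarded stray is rejoined.  Reads where two units claim
more than half of the same span are flagged ambiguous and excluded.

## Stoichiometry

Copy numbers: per-fragment counts (2 kb windows, 0.5 kb step) of reads
with ≥ 1.8 kb alignments at ≥ 80% identity; the length filter excludes
alignments caused by dispersed repeats (all < 1.2 kb).  The interior mean
(trimming two fragments per end, where counts dip because a read must
fully contain a fragment) is divided by an iterated-median single-copy
baseline; copy number is the rounded ratio and ratios > 0.25 from an
integer are flagged rather than silently rounded.  The 0.25 flag band is a
package construction — no published threshold exists for "twice the
coverage".

## Blocks, enumeration and frequencies

Building blocks are counted from unit paths: every length-2 adjacency; a
triple (prev, repeat, next) for every repeat occurrence with both
neighbors detected (neighbors may themselves be repeats — a read needs
only to reach into them); and the maximal window around runs of adjacent
repeats when a read traverses the run.  Blocks under 2 supporting reads
are dropped (chimera/error guard).

Enumeration is a backtracking search over closed walks that consume each
unit exactly copy-number times using only observed adjacencies.  Triples
constrain hinge passage: a walk entering repeat X from A may exit to B
only if A-X-B was observed — *provided* X has at least copy-number
distinct observed triples; with fewer, the hinge was only partially seen
(e.g. a 30 kb repeat that almost no read spans) and is left unconstrained.
Without triple constraints the Eulerian arrangement count explodes; with
them the two-hinge genome yields exactly its two major isoforms.  Results
are canonicalized, deduplicated, and capped (default 10,000) with an
explicit truncation flag.

Frequencies: the support of block b under frequencies f is
s_g · Σ_i f_i n_bi, where n_bi counts occurrences of b in isoform i and
s_g is the detectability of the block's span class (blocks requiring
longer reads are seen less often).  Fractions *within* a span class cancel
s_g, so the fit minimizes the class-support-weighted squared error between
observed and predicted within-class fractions over the frequency simplex
(SLSQP).  Span classes: all pairs together; longer blocks by their
interior unit set.  Isoforms with identical block profiles are genuinely
indistinguishable: they are flagged and their combined frequency is split
evenly.

## Consensus and polishing

Junction re-assembly is draft-anchored: the draft is the concatenation of
the two 3 kb unit flanks; junction-containing reads are trimmed to ≤ 6 kb
centered on the junction offset (segments < 1 kb discarded), aligned to
the draft on their better strand, and voted column by column.  Majority
base wins; ties and columns with < 2 covering segments keep the draft
(stability over novelty); insertions are applied when more than half of
the covering segments agree.  The same pileup polishes contigs with short
reads (minimum depth 3; a warning is raised when > 10% of columns are
thin, and those columns are left untouched).  Polishing is idempotent on
its own output for all test genomes.

## Distance matrices and minor isoforms

Mate pairs (and Hi-C sub-read pairs after splitting reads at GATC-GATC
scars) are mapped by strided 13-mer seed voting; a read maps if its best
(strand, diagonal) placement has ≥ 5 votes and no second placement within
95% of it — the unique-mapping rule that removes reads from repeated
sequence.  Distances use leftmost coordinates and the shorter circular
arc; pairs ≤ 1 kb apart are excluded; matrices are symmetric 1 kb-binned
counts (each pair increments (i,j) and (j,i)), with optional fixed-size
uniform subsamples (320,000 for mate pairs, 640,000 for Hi-C) so libraries
are comparable.

Crossover at a direct repeat (copies at p1 < p2, separation D) creates two
reciprocal junctions whose spanning pairs fall on short diagonals parallel
to the main diagonal at offsets D − I and D + I (I = insert size).  The
estimator sums matrix counts over the triangle of cells
{(a − u, b + v): u, v ≥ 0, u + v ≤ S} at each junction (a, b), where the
span S is the 90th percentile of the matrix's own circular pair-distance
histogram (robust to the signature's own mass), and divides by the mean of
the same triangular flux across reference loci sampled away from the
repeat region.  The ratio estimates the fraction of genomes carrying the
junction — the sense in which an off-diagonal intensity is "a percentage
of the main diagonal".  Copies closer than the library span are flagged
unestimable (the signature merges into the diagonal band).  Calibration by
simulation shows a mild (~15–20%) underestimate from reads lost inside the
repeat and bin-edge effects; planted fractions of 1–50% are recovered
monotonically and a 10% event at a 500 bp repeat is estimated at ~8%.
The exact mask the original analysis used to read frequencies off the
matrix is unpublished; this flux-ratio construction is the package's own,
validated against planted truth.

## Repeat scan

Exact 50-mer seeds on both strands, merged per diagonal, extended
ungapped under +1 match / −20 mismatch with an X-drop of 40, reporting
maximal segments with score ≥ 50 (one full seed).  The raw-score threshold
replaces an E-value cutoff because Karlin–Altschul parameters for this
scoring are not available; with −20 per mismatch, only nearly identical
copies — the recombination-competent ones — survive extension (a 200 bp
copy at 10% divergence scores below zero).  Matches covering ≥ 90% of a
2x unit are classed as hinges; others as dispersed; size classes are
large ≥ 1 kb, intermediate 100–999 bp, short < 100 bp.

## Problem sizes in the test suite

Chosen as the package's own trade-off between statistical comfort and a
reasonable suite runtime:

* Hinge-block recovery: the full saligna-scale mixture at 100× with 15 kb
  reads (one run).
* Frequency recovery: sativa-scale mixtures at 150× with 18 kb reads, two
  seeds per mixture fraction; the recovered fraction is averaged over
  seeds.  At these settings the per-seed estimator error is ~0.02.
* Copy-number recovery: a five-unit genome of 34 kb units (repeat at two
  copies) at 100× with 4 kb reads, 20 seeds.  Units must be several read
  lengths long for the interior coverage mean to beat the read-sampling
  correlation length; 34 kb matches the real repeat scale.
* Minor-isoform detection: a 100 kb circle, 500 bp repeat copies 30 kb
  apart, 5 + 10 kb libraries of 80,000 pairs each (120,000 in the
  acceptance script).
* Oracle comparisons: full Smith–Waterman on ≤ 300 bp instances;
  exhaustive diagonal repeat scan on 6 kb sequences; exhaustive
  arrangement enumeration on graphs of ≤ 8 unit instances.

## Known limitations

* Triple constraints depend on reads spanning a hinge with ~3 kb reach
  into both flanks; hinges much longer than the read length (the 30 kb MN
  repeat) are left unconstrained, and arrangements differing only in such
  a hinge's phasing are enumerated together rather than resolved.
* The frequency model assumes uniform read sampling within a span class;
  strong coverage bias would leak into frequency estimates.
* The recombination-frequency estimator is mildly conservative (see
  above) and requires repeat copies separated by more than the insert
  span.
* The built-in aligner targets high-identity (≥ 80%) alignments; it is not
  a general-purpose sensitive aligner.
* Linear-topology support in enumeration emits open walks but no model of
  terminal-repeat replication (the integrated linear plasmid case is
  handled only as a unit within circular arrangements).
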