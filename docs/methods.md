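# Methods

## The multiplexing model

`amplimux` models a two-step-PCR amplicon workflow. In the first PCR the
target region (e.g. the 16S rRNA gene V4 or V3–V4 region) is amplified with
primers carrying a constant 16-nt *head* (linker) at their 5′ ends — H1
(`GCTATGCGCGAGCTGC`) on the forward primer and either H1 again or H2
(`TAGCGCACACCTGGTA`) on the reverse primer. In the second (barcoding) PCR,
barcode–head fusion primers prepend a fixed-length DNA barcode to one or
both amplicon ends. Every read therefore starts with

    [barcode (8 or 12 nt)] [head (16 nt)] [target primer] [insert …]

Four barcoding layouts are supported, differing in how barcodes identify
samples and hence in multiplexing capacity and crosstalk behaviour for a
barcode set of size k:

| scheme  | heads (fwd/rev) | sample identity            | capacity   |
|---------|-----------------|----------------------------|------------|
| SB      | H1 / H1         | one barcode, both ends     | k          |
| UDB-H11 | H1 / H1         | exclusive unordered pair   | ⌊k/2⌋      |
| UDB-H12 | H1 / H2         | one barcode per side, each used once per side | k |
| CDB-H12 | H1 / H2         | unique *ordered* pair of reused barcodes | k·(k−1) |

With the standard 548-barcode 12-nt set these evaluate to 548, 274, 548 and
299,756 samples per primer pair per pool; `total_capacity` multiplies by the
number of primer pairs (n) and pooled libraries per run (m).

The decisive property is what a single hopped (swapped) barcode does. Under
both UDB layouts, replacing one barcode of a valid combination with any
other barcode in use yields a combination owned by no sample — the read is
flagged (`invalid_combination`), never reassigned. Under CDB, the swapped
pair is typically another sample's valid combination, so the read is
silently misassigned. This is proved exhaustively on small sheets in the
test suite and reproduced statistically by the simulator.

CDB capacity deliberately excludes same-barcode-on-both-sides pairs
(k·(k−1), not k²), matching 299,756 = 548·547. For consistency, UDB-H12
assignment uses a circular offset (forward barcode i pairs with reverse
barcode i+1 mod k), so the two barcodes of a sample always differ even when
a single pool supplies both sides.

The UDB-H11 decoder accepts all four ordered end combinations of a sample's
pair — (a,b), (b,a), (a,a), (b,b) — because a barcoding PCR containing two
H1 fusion primers necessarily produces all four products. This choice keeps
the decoder injective (each combination belongs to exactly one sample
because barcodes are sample-exclusive under UDB-H11).

## Barcode-set design

Barcode sets are judged on two criteria: a minimum pairwise Hamming
distance (default floor 4; the shipped 12-nt design practice reaches min 5,
median 9) and per-position base-composition balance, summarised as
`uniformity_score` = max |freq − 0.25| over all positions × bases (0 =
perfectly balanced, 0.75 = worst).

Because only the criteria, not a procedure, are canonical, `select_barcodes`
uses a seeded greedy max–min build: candidates are shuffled
deterministically, then the next barcode added is always a feasible one
(distance ≥ d_min to all selected) maximising its minimum distance to the
current selection, ties broken by shuffled order. A local swap refinement
then attempts single in/out exchanges that keep the distance floor and
strictly lower the uniformity score (`uniformity_weight = 0` disables
refinement). Uniformity is an *objective*, not a hard constraint — no
numeric threshold is imposed. If no subset of the requested size exists
along the explored path, the largest found is returned with
`reached_target = False` rather than an exception.

Recovering the exact published 549-barcode selection from the 959-candidate
pool is a non-goal (it depends on an unpublished selection order); the
capacity arithmetic uses the 548 barcodes in practical use.

## Demultiplexing

Matching is anchored at read position 0 and indel-free: the construct is
fixed-position and substitutions dominate Illumina error profiles.
Tolerances default to 1 substitution in the barcode and 2 each in the head
and primer; primer matching is IUPAC-aware (an observed base matches a
degenerate pattern base if it lies in its expansion; N matches everything).
`DemuxParams.check_against` warns when `max_mm_barcode ≥ ⌈d_min/2⌉`, the
point at which distinct barcodes can become indistinguishable.

Barcode matching rejects ties: if two set members lie within tolerance of
the observed barcode, the read is `ambiguous`, never guessed. Because
library preparation randomises which physical end becomes R1, dual schemes
are parsed in both orientations (R1 = H1 side, then R1 = reverse side); the
more informative outcome wins, ranked `structural < head_mismatch <
primer_mismatch < unknown_barcode < ambiguous < invalid_combination <
assigned`, and a pair that resolves to two *different* samples in the two
orientations is `ambiguous`. Reads too short to contain
barcode + head + primer get their own `structural` category (distinct from
head/primer mismatches) so that category counts always partition the input.

For SB, the same barcode is expected on both reads: the forward read's
barcode identifies the sample and the reverse read's barcode must resolve
to the same set member, otherwise the pair is an `invalid_combination`.

Trimming removes barcode + head + primer; qualities are carried through
untouched (no quality filtering — denoising is deliberately out of scope).
Per-sample outputs are orientation-normalised: `<sample>_R1.fastq.gz`
always holds the H1-side insert in template orientation, which makes exact
dereplication orientation-stable. Yield is assigned pairs over total pairs,
before any quality filtering.

## The synthetic-data generator

`synthetic_amplicons` emulates a multiplexed run end to end: multinomial
template sampling, scheme-correct read construction (degenerate primer
positions resolved uniformly at random per read; reverse-side inserts
reverse-complemented), independent per-base substitution errors at rate ε,
and barcode hops at rate ρ. Every emitted pair is recorded in a manifest
(true sample, true template, injected edits, swap events) — the ground
truth for round-trip and misassignment measurements. All randomness derives
from one master seed through five named substreams (composition,
construction, crosstalk, errors, shuffling), so runs are byte-identical
given the same configuration (gzip members are written with a zeroed
timestamp).

Default study conditions: 2,438 read pairs per mock draw, and 100
replicates for count-only simulation (`simulate_mock_counts`), matching the
standard mock-community simulation design. The built-in
`default_mock_reference()` is a *synthetic* staggered community: eight
members with 10-fold log-spaced abundances, the two most abundant carrying
two intragenomic 16S variants (5 substitutions apart, 60/40 within the
species), sequences being random 150-mers. It mirrors the design of
commercial log-distribution DNA standards, not their real sequences or
exact per-gene weights; per-variant weights are always an input, never a
computation.

The hop model replaces exactly one side's barcode per event with a barcode
in use on that side by a *different* sample, excluding the barcode on the
un-swapped side (a hop reproducing the pair's own other tag is not
between-sample crosstalk; the exclusion also makes the fully-used-CDB limit
exact: at ρ = 1 every swapped pair is another sample's valid pair). If the
chosen side has no legal replacement — possible on very small sheets — the
other side is used, keeping the effective event rate at ρ. Double hops can
be composed by applying the injector twice.

What the generator does *not* emulate — and therefore what passing tests do
not establish about real data: PCR chimeras, amplification/primer bias,
indels, quality-score decay, real 16S sequence structure, and real
index-hopping mechanisms (which correlate with free-adapter concentration
rather than being i.i.d. per read). The simulator validates the
*bookkeeping and combinatorics* of the schemes, not sequencing chemistry.

## Evaluation metrics

Count tables are pandas DataFrames (rows = unique insert sequences, columns
= samples) built by exact dereplication of demultiplexed reads — the
denoising-free analogue of an ASV table, appropriate because synthetic
reads need no error modelling.

* **Reference matching**: a sequence is attributed to a mock variant when
  within 1 substitution of an equal-length reference variant (Hamming, not
  local alignment — synthetic inserts are fixed-length; an alignment
  backend is a pluggable extension point). Everything else is spurious; in
  PCR negative controls *every* detected sequence is spurious.
* **Alpha diversity**: observed richness (#nonzero) and bias-corrected
  Chao1, S_obs + f1(f1−1)/(2(f2+1)) (scikit-bio's implementation; the
  bias-corrected form matches common ecology-package defaults). Chao1 ≥
  observed always, with equality iff f1 ≤ 1.
* **Bray–Curtis**: Σ|x−y| / Σ(x+y) via scipy; undefined for two all-zero
  vectors (raised as an error).
* **Rarefaction**: multivariate-hypergeometric subsampling without
  replacement (numpy Generator), deterministic per seed;
  `rarefy_table` defaults to the smallest column depth.
* **Abundance filter**: drop rows that never *strictly* exceed the
  relative-abundance threshold (default 0.25%) in any sample; the boundary
  case (exactly at threshold everywhere) is dropped. Surviving rows keep
  raw counts.
* **Expected vs measured**: per amplicon pool, reads are summed across the
  pool's libraries, variants are aggregated to species, and Pearson r is
  computed between log measured and log expected relative abundances over
  the species detected in that pool (undetected species excluded — no
  pseudocount; natural log, though any base gives the same r). Pools with
  fewer than two shared detected species are skipped with a warning. An
  `exclude_species` list supports manual curation of presumed external
  contaminants.
* **Mock-sequence prevalence** (`mock_sequence_prevalence`): the fraction
  of non-mock samples containing at least one mock-matching sequence. This
  is an interpretation — it operationalises "mock-specific sequences
  detected outside mock libraries" as a per-sample presence flag — and is
  exposed separately rather than folded into the spurious report.

## Problem sizes and numerical choices

The test suite validates the scheme combinatorics exhaustively at small
scale (capacity vs brute-force enumeration for k ≤ 30; decoder injectivity
and single-substitution safety over all combinations of 6-sample sheets)
and the pipeline statistically at moderate scale: round-trip fidelity on
10 samples × 1,000 read pairs per scheme, and the UDB/CDB crosstalk
contrast on 12-sample sheets (4 mock replicates, 6 samples with
sample-specific templates, 2 blank negative controls) at 600 read pairs
per sample and ρ = 0.01, with binomial (3σ) tolerances on stochastic
counts. These sizes give stable verdicts for seeded runs while keeping the
whole suite fast; all stochastic assertions use fixed seeds.

Tie-breaking is deterministic everywhere: greedy selection breaks ties by
shuffled input order, barcode matching by rejecting ties outright,
crosstalk replacement by seeded choice from a sorted candidate list.
Degenerate inputs raise typed errors rather than returning sentinel values
(empty barcode sets, mixed lengths, depth > total in rarefaction, both-zero
Bray–Curtis, probabilities not summing to 1).

## Known limitations

* Anchored matching cannot rescue reads with indels in the technical
  prefix; such reads fail head or primer matching.
* The simulator's i.i.d. hop model quantifies scheme *detectability*, not
  real hop rates; absolute spurious-sequence counts are not comparable to
  wet-lab runs.
* Sequencing-run yields and group-significance statistics from real
  datasets are outside the package's scope, as are denoising (DADA2-style),
  chimera removal, PCoA ordination and plate-map exports.
* A sample sheet is assumed to use one primer pair per pool; mixed-primer
  pools must be demultiplexed per primer pair.
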