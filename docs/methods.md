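# Methods

`pancent` analyses the tandem-repeat satellite arrays that make up plant
centromeres: it extracts individual satellite monomers from assembled
sequence or sequencing reads, quantifies their diversity and duplication
structure, profiles CENH3 occupancy over them, mines higher-order repeat
(HOR) units, and relates satellite divergence to retrotransposon (CRM)
invasions. A fully seeded synthetic generator provides chromosomes with
planted ground truth so that every estimator can be validated as a
parameter-recovery problem.

## The synthetic centromere model

A chromosome is: random flank — satellite array (optionally interrupted by
CRM elements) — random flank. The array is either `n_copies` tandem copies
of one consensus monomer or a HOR unit (an ordered tuple of monomer
variants, each a fixed substitution set on the consensus) tiled
`unit_copies` times. Each copy is then independently mutated:
substitutions are per-site Bernoulli events that never reproduce the
original base, indels are single-base insertions or deletions (the 1-bp
scale matches the indel spectrum seen between closely related satellite
consensuses). Strand blocks are reverse-complemented as whole blocks
*after* mutation, so orientation and divergence are independent.

CRM elements are inserted at monomer-copy boundaries. Each element is a
random internal sequence flanked by an LTR pair descended from a single
ancestral copy; each LTR accumulates substitutions at per-site probability
`r * T` (clock rate `r`, age `T` in years), so the expected pairwise LTR
divergence is `K = 2 r T` — the quantity the dating estimator inverts.
Monomers within `flank_window` bp of an insertion mutate at
`sub_rate * flank_hypermutation_factor`, emulating the elevated satellite
divergence observed around retrotransposon insertions.

ChIP/Input reads: Input fragment midpoints are uniform; ChIP midpoint
density is `fold` times background inside the centromere and, within each
monomer, weighted by a von-Mises-like periodic factor
`exp(kappa * cos(2*pi*(offset - phase_offset)/L))`, normalized to mean 1
over the monomer so the interval-level fold is preserved. No published
functional form exists for the phased CENH3 signal; the von-Mises shape is
the natural circular unimodal choice and `kappa` is configurable
(default 8, a peak with ~15 bp half-width). Fragment lengths are
Normal(156, 15) truncated to [read_length, 2*read_length] — the MNase
mononucleosome scale — with 101-nt paired-end reads and constant Q40
qualities; a uniform sequencing-error rate is available but off by
default, since the error model is not the object of study.

Default study conditions (chosen once): 156-bp consensus at GC 0.45,
500 copies, substitution rate 0.02/site/copy, indel rate 0.002, ChIP fold
8, phase offset 80 bp, coverage 20x, clock rate 1.3e-8 subs/site/yr (the
grass-standard LTR clock), CRM age 0.5 Mya. Everything derives from one
integer seed and identical configurations produce byte-identical
FASTA/FASTQ/truth outputs.

What the generator does *not* model: homogenization dynamics (arrays are
generated, not evolved through unequal crossover), mappability and
alignment artifacts (fragment coordinates are known, so no aligner is in
the loop), PCR duplicates, and base-composition biases. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to every artifact of real libraries.

## Monomer extraction

Monomers are cut at a *shared consensus phase*: the consensus is first
rotated to its lexicographically smallest form (`canonical_rotation`),
and all boundaries are placed at position 0 of that rotation. This makes
monomers comparable across arrays, which the monomer-by-monomer statistics
(variant labeling, phasing, k-mer vectors) require.

`decompose_array` seeds each array with the best semi-global placement of
the consensus anywhere in the (both-strand) sequence, then walks outward
one monomer at a time with prefix-anchored alignments (edlib `SHW`): each
step aligns the full consensus starting exactly at the previous boundary
with a free end, accepting the step if alignment identity reaches
`min_identity` (default 0.6). Found spans are masked and seeding repeats,
so multiple arrays and whole reverse-orientation blocks are handled.
Monomers separated by at most `max_gap` (default 2 kb) share an
`array_id`; CRM-scale insertions (typically >> 2 kb) therefore terminate
arrays. Identity is everywhere defined as matching columns over total
alignment columns, with gap columns counting against identity.

The 0.6 identity floor sits close to the best-local-alignment identity of
random sequence, so an occasional spurious monomer can appear in random
flanks (< 1 % of copies in practice); recovery statistics therefore
measure whether every *planted* monomer is found at its position, with
extras absorbed by the count-error figure.

The read route merges overlapping mate pairs (best overlap by mismatch
rate, at least 10 bp overlapping at <= 10 % mismatches), keeps merged
fragments of 146–166 bp (inclusive bounds — the mononucleosome window),
and assigns fragments to a consensus by local alignment (+1/−2 match/
mismatch, gap open 5 / extend 2) against each consensus doubled (so
alignments may span the arbitrary phase junction), on both strands. The
best score is converted to an E-value with ungapped Karlin–Altschul
statistics: lambda is solved numerically from
`(1/4) e^{lambda} + (3/4) e^{-2 lambda} = 1`, K = 0.621, search space =
fragment length x total doubled-consensus length x 2 strands. Fragments
with E <= 1e-5 are labeled; ties break by higher identity, then name.

`build_consensus` recovers a consensus by center-star alignment against
the medoid of a deterministic 30-member sample, majority voting per
column (center-relative insertions kept only with majority support), and
canonical rotation of the result. At 2 % noise and n >= 200 the vote
recovers the planted consensus exactly.

## Diversity statistics

* **Identity to consensus** — semi-global alignment of the monomer
  against the doubled consensus (best circular phase); identity =
  matches / columns.
* **SNP/indel counts** — optimal global alignment under unit costs
  (match 0, mismatch 1, gap 1), implemented as a three-state DP whose
  cost is lexicographic in (edits, gap openings) with a deterministic
  traceback: among co-optimal alignments the one with the fewest gap
  openings (then leftmost gaps) is counted. SNPs are mismatch columns;
  indels are maximal single-side gap runs. This tie-break is the reason
  the aligner is hand-written rather than delegated.
* **Duplication / sharing** — "identical monomers" means exact string
  equality after strand normalization (a sequence and its reverse
  complement are the same monomer). Proportions count monomers with at
  least one duplicate in the scope, self excluded within chromosomes.
  Exactness is deliberate: it makes the statistic a crisp predicate that
  brute-force oracles can verify.
* **5-mer PCA + HCA** — linear 5-mer counts per monomer (windows with
  non-ACGT symbols dropped), row-normalized; PCA on mean-centered,
  unscaled frequencies (frequencies share a scale; variance-scaling 1024
  sparse columns amplifies noise); Ward/Euclidean agglomerative
  clustering on the first <= 100 components, labels renumbered by first
  occurrence for determinism. Both the centering choice and the linkage
  are configurable in principle; the defaults are what the package
  validates.
* **Group comparisons** — Welch's unequal-variance t-test, two-sided; the
  degenerate all-constant-equal case returns p = 1 by convention.

## Enrichment profiling and centromere calling

Coverage is binned (per-bin mean depth; terminal bins average their true
width), each library is normalized to genome-wide mean depth 1 — making
the log2 ratio exactly invariant to sequencing depth — and the track is
`log2((chip + p) / (input + p))` with pseudocount p = 0.5 in
normalized-depth units, which keeps zero-input bins finite.

The centromere of a chromosome is operationalized as: threshold the track
at log2 >= 1, merge passing bins across gaps <= 100 kb, return the region
with the maximal summed signal (one call per chromosome; chromosomes are
treated as monocentric). The enrichment level of a call is the mean
normalized ChIP depth inside it divided by the genome-wide mean — exactly
1.0 on a uniform track, and for a planted fold F over genome fraction f
it equals `F / (1 - f + f F)` (library normalization compresses the raw
fold; the 10-kb calling bin and the verbal definition are repo choices).

Repeat clusters are centromeric when normalized ChIP/Input ratio > 2.6
AND genome fraction > 0.5 %, both strictly. Quantile grouping splits
monomers into 5 near-equal groups by decreasing occupancy or identity
(stable ties). Metaprofiles rescale each feature body to a fixed bin
count (per-base means per segment), keep flanks at native bin resolution
and flip minus-strand features before averaging.

`phase_profile` maps each ChIP fragment midpoint inside a monomer to its
strand-aware offset (rescaled to the modal monomer length when indels
change a copy's length) and returns the raw per-offset density plus the
argmax of a circularly smoothed copy (5-bp moving average). The raw
density is what uniformity tests consume; the smoothing only stabilizes
the argmax against bin-level shot noise.

## HOR mining

Monomers are labeled into variant classes by greedy first-fit clustering:
a monomer joins the first representative within the identity threshold
(default 0.95), else founds a new label. A refinement pass (on by
default) rebuilds each label's representative as the majority consensus
of its members and reassigns every monomer to its best representative at
or above the threshold — never comparing a monomer to a representative
derived solely from itself. The pass exists because a founding copy
carries its own noise: two noisy copies of the same variant can fall
below threshold of each other even when both are within threshold of the
variant's true sequence; voting the noise out makes exact HOR recovery
reliable at 1 % noise. `refine=False` restores the strict single pass.

HOR units are mined per array from the label string: for every primitive
unit (not itself a repetition of a shorter tuple) of length <= 20,
maximal tandem runs with >= 2 copies are collected, ranked by copy number
(ties: longer unit, then leftmost) and selected greedily without overlap;
the top 5 are reported by default. Unit length 1 is allowed — runs of one
variant are monomic expansions, a prominent feature of real arrays. This
is a deliberately simple, deterministic annotation, not a reimplementation
of hierarchical HOR-merging tools.

## CRM dynamics

LTR divergence is the p-distance over aligned (non-gap) columns of the
globally aligned LTR pair, with the Jukes–Cantor correction
`K = -(3/4) ln(1 - 4p/3)` by default (undefined at p >= 0.75; raw
p-distance available) — JC69 is standard for young elements and within a
percent of raw below K = 0.05. Insertion age is `T = K / (2r)` in Mya at
the default clock `r = 1.3e-8` subs/site/yr.

`crm_adjacent_identity` partitions monomers exhaustively into "near"
(overlapping any element +/- window, default 5 kb in the API and 2 kb in
the planted-effect analyses, matching the generator's hypermutation
window) and "interior", and reports a Welch t-test.
`ltr_density_vs_identity` tiles the chromosome with fixed windows
(100 kb default; 10 kb in the compact synthetic analyses), computes LTR
bp density and mean monomer identity per window (windows with < 10
monomers excluded — mean identity is unstable on tiny samples), and
reports Pearson r with its two-sided p.

## Problem sizes and numerical choices

The validation analyses run at deliberately compact scales: 500-copy
arrays (~80 kb) for recovery statistics, a 6,410-copy array in a 5-Mb
chromosome for centromere calling (1-Mb centromere, 10-kb bins), 600
fragments for family separation, and 100 seeded replicates for the null
calibration of the flank-hypermutation test. These sizes put Monte-Carlo
noise well inside the stated tolerances while each analysis completes in
seconds. All randomness flows from `numpy.random.default_rng` seeded from
a single integer; tie-breaks (alignment traceback, label order, ranking)
are fixed so outputs are reproducible bit-for-bit.

## Known limitations

* The decomposition walk assumes arrays stay near the consensus length;
  grossly diverged or truncated copies (below the identity floor) end an
  array rather than being annotated as partial monomers.
* E-values use ungapped Karlin–Altschul constants with gapped scores — the
  standard practical approximation, adequate for a 1e-5 cut-off but not
  calibrated for marginal hits.
* The HOR scan reports tandem runs only; interspersed or inverted HOR
  relationships are out of scope.
* Dating noise on short LTR pairs is binomial in the LTR length: a 400-bp
  pair at 0.5 Mya carries ~5 expected substitutions, so single-element
  ages scatter by tens of percent; class means are the meaningful output.
* Null calibration of the adjacency t-test is exact only under the
  generator's independence assumptions; spatially autocorrelated
  divergence in real arrays would inflate the test's false-positive rate.
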