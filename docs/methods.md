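# Methods

## Promoter windows and coordinates

All genomic coordinates are handled 0-based half-open internally (GFF3
input is 1-based inclusive, BED 0-based half-open).  The transcription
start site is relative position 0 and the default analysis window is
[−1000, +200), i.e. 1,200 nt with the TSS base as the first transcribed
position.  Minus-strand genes are reverse-complemented so every promoter
reads 5′→3′ toward and into the transcript.  Windows that cross a contig
edge are truncated: the realized relative window is recorded on the
record and a `truncated` flag is set, so the `length == end − start`
invariant holds for every emitted sequence.  The TSS is taken verbatim
from the input annotation (the annotation's source string is kept as
provenance); no TSS inference is attempted.  The transcribed +1..+200
portion is scanned like the rest of the window regardless of any coding
overlap.

## Matrix model and similarity scores

A binding-site matrix is a position frequency table over {A,C,G,T},
6–8 nt in this domain.  Raw counts get a pseudocount of 0.5 per cell
before normalization (rows that already sum to 1 are taken as
probabilities verbatim, which makes written libraries round-trip
bit-faithfully).  The conservation weight of position *i* is
`ci(i) = (100/ln 4)(ln 4 + Σ_b f(i,b) ln f(i,b))` with 0·ln 0 := 0 —
an affine rescaling of the position's Shannon information to [0, 100].

`mat_sim` is the ci-weighted frequency of the observed bases divided by
the ci-weighted frequency of the per-position consensus, so exactly the
windows selecting an argmax base at every position score 1.  `core_sim`
restricts the same ratio to the matrix core: the contiguous run of 4
positions with maximal summed ci, leftmost on ties.  A matrix with no
information anywhere (all rows uniform) scores 0 by convention.  `N`
bases contribute 0 at their position and are never an error.  All
threshold comparisons use a 10⁻⁹ slack so windows sitting exactly on a
threshold are classified identically regardless of floating-point
summation order.

Defaults: core_len 4, core threshold 0.75, matrix threshold 0.85.  A
library file may carry per-matrix "optimized" thresholds which then take
precedence; the bundled synthetic library sets 0.75/0.88 (0.88 admits
single-mismatch windows for its 8-nt matrices only, so sampled planted
sites exercise score variation while 6–7 nt matrices stay
consensus-strict).

## Exact site significance and the e-value scale

The null model is i.i.d. background (composition estimated from the
scanned promoter set, or fixed, e.g. uniform).  The probability that a
random L-mer passes *both* thresholds is computed exactly: the 4⁴ core
assignments are enumerated outright, and the non-core positions are
convolved by a sparse-sum dynamic programme over reachable partial
scores, accumulated in the same position order as the scanner's own
summation.  For L ≤ 10 the state space is tiny and the result matches
exhaustive 4^L enumeration bit-for-bit — the test suite asserts exact
agreement for every library matrix; an optional granularity parameter
can coarsen the states for much longer matrices.  This is exact
computation, not sampling.

Each hit reports `evalue = p_site × 2 × (len − L + 1)`, the expected
number of chance hits of its matrix in the scanned promoter (both
strands).  The significance filter, however, applies its cutoff
(default 10⁻³) to `p_site`, not to the expected count: for a 6–8 nt
matrix the expected chance-hit count in a 1,200-nt window is bounded
below by `2·1193·4⁻⁸ ≈ 0.036` even for a perfectly specific matrix, so a
10⁻³ cutoff on the expected-count scale would discard every matrix of
this size unconditionally.  On the per-site scale the same cutoff
retains specific matrices (consensus-only 6-mers have p ≈ 2.4×10⁻⁴) and
rejects degenerate ones, which is the only reading under which a 10⁻³
threshold does any work for short motifs.  `cutoff_scale="promoter"`
switches to the literal expected-count filter for completeness.  Both
the cutoff and the scale are echoed in result-bundle metadata, along
with a formula-version string identifying the scoring scheme.

## Occurrence matrices and conservation categories

TFBS occurrence is binary: 1 for one-to-many retained hits of any matrix
of a class in a promoter, 0 for absence.  Classes never observed are
dropped from the matrix but logged and recorded.

Within one COG every class present in at least one member promoter gets
exactly one category, applied in this precedence: **I** present in every
ortholog and ≥1 paralog; **II** present in every ortholog, absent from
all paralogs; **III** present in every ortholog of exactly one
multi-species lineage, absent elsewhere and from paralogs; **IV**
present in the ortholog(s) of exactly one species, absent elsewhere and
from paralogs; **P** present only in paralogs; anything else is
`unclassified`.  The paralog-absence requirement is applied to IV as
well as III, so "unique to a species" means unique among all genes of
the group; the count summaries offer an `include_paralog_carriers`
switch for the laxer reading (unique among orthologs only).  Species
with several gene copies count as present when any copy carries the
class; a stricter all-copies mode is available.  A COG without paralogs
cannot express I or P: all-ortholog classes are reported as II, which
also gives the clean identity "removing all paralogs turns every I into
II and leaves III/IV unchanged".

The Table-style summary reports, per COG, the number of classes present
in every member species and the per-species unique counts; chi-square
tests compare those unique counts against 1:1:1 (all species) and 1:1
(each pair) as plain Pearson goodness-of-fit statistics without
continuity correction, df = cells − 1.  Significance stars (\*, \*\*,
\*\*\* at p < 0.05 / 0.01 / 0.001) are always recomputed from the exact
p-value rather than transcribed.  No multiple-testing correction is
applied by default (a Bonferroni option exists) — matching how such
tables are conventionally reported in this literature.

## Core-module detection

Candidate arrangements ("site chains") are subsequences of a promoter's
deduplicated (position, class, strand) site list: intervening extra
sites are explicitly allowed, which is an assumption the output flags by
construction (chains are keyed only by their own class/strand signature).
Chains are constrained by k ∈ [2, 4] sites, consecutive start-to-start
gap ≤ 150 nt and overall span ≤ 400 nt by default — values chosen to
bracket visually tight module spacings in this literature; all are
configurable and echoed in the output.

A module is emitted for a class/strand signature when (i) every ortholog
carries a chain with that signature, (ii) each member's consecutive gaps
differ from a reference instance's gaps by at most the tolerance
(±10 nt default), and (iii) no paralog chain with the same signature is
gap-compatible with that reference.  Spacing is compared pairwise
against the reference (the lexicographically first ortholog's chain)
rather than mutually, because pairwise-within-tolerance is not
transitive.  Maximality suppresses signatures that are contiguous
sub-sequences of another emitted signature; a non-contiguous
sub-arrangement (e.g. first and third site of a 3-site module, with its
own conserved spacing) is a distinct valid signature and may be emitted
alongside.  Absolute distance from the TSS is never a detection
criterion — it is reported per member (anchor positions) for downstream
inspection, since conserved modules legitimately sit at different TSS
distances in different species.

Neither the paralog-absence veto nor maximality is monotone in the gap
parameters (a looser tolerance can let a paralog chain match and kill a
module; a larger max_gap can create a longer module that absorbs a
shorter signature), so the monotonicity guarantee — enlarging max_gap or
gap_tolerance never removes a detected signature — holds for the
paralog-free, non-maximal detector and is tested there.

`brute_force_core_modules` implements the identical contract by raw
combination enumeration and naive quantifier loops, guarded to ≤ 25
sites per promoter; it exists purely as an independent oracle and the
suite checks detector/oracle identity on hundreds of randomized
instances.

## Hierarchical clustering

Binary profiles are compared by Jaccard distance (1 − |∩|/|∪|, 0/0 := 0)
or Hamming distance; clustering is agglomerative with average (default),
complete or single linkage.  The agglomerator is written in-package
(O(n³), n is tens here) because its contract fixes the tie rule — among
equidistant cluster pairs the one whose smallest leaf labels sort first
merges — making topologies a pure function of the labelled distances;
scipy's linkage serves as an independent cross-check on tie-free inputs
in the tests.  Merge heights are the linkage distances; Newick export
assigns ultrametric branch lengths (leaf-to-root depth = final height/2).

## Synthetic data: what it emulates and what it does not

The generator produces the structure the analysis assumes: per COG, one
1,200-nt promoter per ortholog species (two monocots, one dicot by
default) plus paralogs; spatially conserved modules planted with fixed
class order, strand pattern and nominal gaps (+ rounded Gaussian jitter,
sd 0 or 3 nt in the shipped experiments; anchors drawn uniformly from
−700..−300); and singleton classes planted in each category pattern.
Sites are drawn from the matrix distribution *conditional on exceeding
the scan thresholds* by default (consensus and unconditional sampling
are switches) so that planted sites are bona fide sites by the
detector's own definition.

Planted truth is exact by construction: background is scrubbed of chance
matrix matches at the scan thresholds before planting (bounded redraw of
offending windows), and every finished promoter is verified — the set of
(class, position, strand) detections at the design thresholds must equal
the planted set, with a bounded regeneration on residual junction
artifacts.  This is what makes "recall 1.0 at zero jitter" and "100%
correct category labels" meaningful, decidable statements: for 6–8 nt
motifs a raw random 1,200-nt background yields chance consensus matches
at a rate (~0.04–0.6 expected hits per promoter and matrix) that would
otherwise corrupt presence/absence categories in a sizable fraction of
replicates.  Consequently, passing these experiments demonstrates the
correctness of the machinery on planted signal, *not* detection power on
real promoters, where chance hits, correlated background composition,
binding-site turnover and alignment uncertainty all exist.  An
order-1 Markov background and an unscrubbed mode are provided; the
unscrubbed false-positive rate is itself checked against the summed
per-matrix e-values (Poisson band) in the suite.

The bundled library is synthetic: 26 classes (three of them represented
by a second, weaker matrix), lengths cycling 8/6/7 nt, dominant-base
probability 0.85 (0.80 for the duplicates).  Consensus sequences are
generated from a fixed internal seed under the constraint that every
sliding alignment of any two consensi (either strand, including
self-overlaps and reverse-complement self-matches) with ≥4 bases of
overlap carries ≥2 mismatches — so no planted site of one class can
systematically trigger another class at the library thresholds.  Class
names reuse familiar plant cis-element family mnemonics purely for
readability; the matrices do not model the real elements.

## Validation experiments (what the suite computes)

* Chi-square reproduction: published per-species unique-count cells are
  recomputed; 29 of the 36 printed statistics agree with plain Pearson
  recomputation to the printed 3-decimal precision (tolerance 0.0015 =
  one unit in the last printed digit) and are asserted exactly; the 7
  deviating cells are asserted to deviate (presumed typos in the source
  table) and excluded from reproduction.
* Scanner oracle: exact DP vs exhaustive 4^L enumeration, every library
  matrix, two thresholds, two backgrounds — equality to ≤1e-13.
* Module oracle: detector ≡ brute force on 200 randomized instances
  (2–3 orthologs, 0–2 paralogs, ≤ ~15 sites each, 60% with a planted
  shared arrangement).
* End-to-end: 20 seeded replicates (2 COGs each, 2- and 3-class modules)
  at zero jitter → module recall 1.0 and all planted category labels
  correct; 20 replicates at jitter sd 3 / tolerance 10 (2-class modules)
  → recall ≥ 0.9 (binomially ≈ 0.97 expected: each member's realized
  gap differs from the reference by N(0, √18), |Δ| ≤ 10 with p ≈ 0.987).
* Monocot proximity: in every replicate and COG the two monocot ortholog
  leaves merge before the dicot leaf in the Jaccard/average gene-axis
  dendrogram — guaranteed structurally by the monocot-shared (III)
  plantings and asserted over all 40 COG instances.

Problem sizes were chosen so the whole suite runs in about a minute and
the acceptance script in a few minutes on one CPU.

## Known limitations

* The similarity formulas are a reconstruction of the conservation-
  weighted core/matrix scheme long used by commercial plant-promoter
  scanners; vendor implementations differ in unpublished details
  (core length, threshold optimization), so absolute scores are not
  interchangeable with any proprietary tool's output.
* The e-value null is i.i.d. (or the provided order-1) background; real
  promoters are not i.i.d., so reported e-values understate chance-hit
  rates in repetitive or skewed sequence.
* Module detection treats sites as points (start positions); it does not
  model overlapping-site exclusion or site length in spacing.
* Binary occurrence discards copy number and position for the category
  and clustering analyses by design.
* The pipeline's stage cache keys hash configuration and inputs; editing
  bundle files by hand defeats provenance (checksums will expose it).
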