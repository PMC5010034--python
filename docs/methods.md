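# Methods

This note documents the models and procedures implemented in `bipolarmeth`,
the defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Per-read pattern extraction

Coordinates are 0-based half-open everywhere internally; a CpG is addressed
by the forward-strand C, and calls from reverse-strand reads (which sit on
the G of the dyad) are projected onto the forward C, the usual Bismark
convention. Pattern extraction slides a window over every run of four
*consecutive* CpGs of the reference CpG map that a read calls unambiguously;
a read with an ambiguous or missing call inside a window is excluded from
that window only, never globally, which maximizes usable depth without
imputing states. Pairs of mates are treated as independent reads; windows
never span mates.

PCR deduplication keeps the first read per `(chrom, start, strand,
aligned-length)` key. The criterion is not uniquely defined by upstream
tools, so the key is explicit here and the operation is idempotent by
construction.

## Bipolar classification

Eligibility (the *prefilter*) requires depth ≥ 10 at the 4-CpG segment —
counting only reads that cover all four CpGs — plus at least one fully
methylated and one fully unmethylated read concurrently. Depth counted this
way is the stricter of the two readings of "10× coverage" and is the one
the pattern multiset naturally provides.

The classifier models per-read methylated-CpG counts k ∈ {0..4} as a
mixture of Beta-Binomial components with n = 4 trials.

* `dp_gibbs` (default): Dirichlet-process mixture, concentration α = 1,
  Beta(½, ½) base measure, 200 collapsed-Gibbs sweeps of which the first
  100 are burn-in. Each retained sweep is scored as bipolar if its cluster
  state contains a component with posterior mean (S + ½)/(4m + 1) ≤ 0.25
  and one ≥ 0.75, each with weight ≥ 0.10; the call is the majority vote
  over retained sweeps. The vote is a posterior-probability estimate of the
  same event a single-sweep snapshot would read off, with far less sampling
  noise; it is bit-reproducible given the seed because each cluster derives
  its RNG stream from (seed, segment key), independent of processing order.
  Clusters deeper than 500 reads are subsampled (seeded) before sampling to
  bound runtime.
* `em_bic`: finite mixtures K = 1..3 of Binomial(4, p) components
  (Beta-Binomial with no extra dispersion — with only five distinct
  outcomes per read, within-component overdispersion is not identifiable
  at these depths), deterministic quantile initialization, EM with a
  Beta(½, ½)-posterior-mean M-step to keep p off the boundary, BIC model
  choice. Fully deterministic; roughly 3× faster than the sampler.
* `lrt_oracle`: every threshold partition of k seeds a two-component EM;
  the best fit is kept only if BIC prefers it over one component. This is
  the slow exhaustive reference used in the tests.

The bipolarity thresholds (hypo ≤ 0.25, hyper ≥ 0.75, weight ≥ 0.10) are
exposed configuration. They bracket "fully methylated / fully unmethylated"
molecules with tolerance for bisulfite conversion failure: a component of
truly unmethylated molecules with a 99.7% conversion rate has mean ≈ 0.003,
far below 0.25, while a 0.25/0.75 pair cannot both be produced by one
intermediate component. The weight floor keeps one stray read at depth 10
(weight 0.1) on the boundary: a single opposite-state molecule is exactly
the evidence the prefilter demands, so it is deliberately not excluded.

Calls on chrX/chrY are dropped (X-inactivation produces allele-level
bipolarity) as are calls overlapping known imprinted intervals by ≥ 1 bp.
Overlapping surviving segments merge into CSM regions by transitive closure
of strict overlap; abutting segments share no base and stay separate.

Profiles of bipolar status across samples are compared by Pearson
correlation restricted to segments with defined status in both samples
(zero-variance vectors give NaN, not 0) and clustered with average linkage
on 1 − r; sample order is fixed lexicographically so dendrogram ties break
deterministically.

## Hairpin reconstruction

A hairpin library ligates a loop adapter joining the two strands of a
molecule, so read 1 carries the converted top arm and read 2 the converted
bottom arm. Trimming searches each read's 3' side for a prefix of the loop
or sequencing adapter with ≥ 8 bp overlap and ≤ 10% mismatches. Matching is
bisulfite-aware and *orientation-specific*: forward queries tolerate query-C
vs read-T, reverse-complement queries tolerate query-G vs read-A. Allowing
both tolerances on every query would make half the alphabet a wildcard and
produced spurious internal adapter hits in testing.

Arms are aligned globally (Needleman–Wunsch via Biopython's PairwiseAligner
with a custom asymmetric substitution matrix; match +1, mismatch −1, linear
gap −2). In the top frame, top-strand conversion appears as T-over-C and
bottom-strand conversion as G-over-A; both column types score as matches
and count as identical. Identity is computed after trimming terminal
overhang columns; pairs below 90% identity are rejected and counted.
Original bases are resolved per column — a bottom-frame C pins the original
to C (top read C ⇒ methylated, T ⇒ unmethylated), a top-frame G pins it to
G (bottom G ⇒ methylated, A ⇒ unmethylated) — and every CG of the recovered
sequence yields a dyad with two strand states, `.` where a strand is
gapped or uninformative.

Fidelity is the fraction of fully-called dyads with identical strand
states. Methylation level counts both strand-calls of each dyad
individually (inherited convention from the hairpin literature). For
sliding windows of w adjacent called dyads within one molecule: symmetric =
both strands uniform and identical, asymmetric = both strands uniform and
opposite, all other windows count in the denominator only. At w = 1 every
window is one or the other, so fidelity = 1 − asymmetric fraction exactly —
this identity is asserted in the tests. The w > 1 denominator choice (all
windows, not only strand-uniform ones) is a package decision; it reproduces
the w = 1 identity and makes the independence closed form below exact.

Feature profiles cut each stranded feature into 20 equal bins (5'→3' along
the strand) and report per-bin level and fidelity; features shorter than
the bin count are skipped with a warning. The conversion rate is estimated
from unmethylated spike-in molecules as converted / total C calls.

## Down-sampling normalization

Detection of a bipolar pattern is depth-dependent (deeper samples are more
likely to catch both extreme molecules), so cross-sample frequencies use
only segments ≥ 10× in *every* sample, subsampled without replacement to
the per-segment minimum depth D_min, 100 repeats. Detection probability is
the fraction of repeats in which the prefilter and (by default) the full
classifier fire; a prefilter-only mode exists and is checked against the
exact hypergeometric probability in the tests. RNG streams derive from
(master seed, sample, segment, repeat), so adding a sample never perturbs
existing estimates, and estimates are invariant to pattern input order.
The per-sample normalized frequency is the mean detection probability over
common segments; a "count of segments with probability > 0.5" aggregation
is available as configuration, since the aggregation is a convention rather
than a derived quantity.

## Annotation and enrichment

Promoters are the 2 kb upstream of each TSS, strand-aware, split into CGI
and non-CGI by ≥ 1 bp CpG-island overlap. Histone peaks (H3K4me1, H3K4me3,
H3K27ac) merge into merged-peak regions labeled by precedence: H3K4me3 ⇒
active promoter (CGI/non-CGI), else H3K27ac ⇒ active enhancer, else
H3K4me1 ⇒ poised enhancer. Gene association takes genes with ≥ 1 bipolar
segment within 10 kb of the TSS against a background of genes with ≥ 1
eligible segment in the same window.

The SNP enrichment null circularly shifts all regions of a chromosome by
one shared uniform offset per iteration, preserving region count, lengths
and spacing — the conservative joint-shift variant; per-region shifts are a
configuration option. Regions are extended ±100 bp before shifting and a
SNP counts within 100 bp (inclusive) of an extended region. The p-value
uses the add-one estimator (1 + #{null ≥ obs})/(1 + N), never zero at
finite N. An exhaustive mode enumerates every offset of a single
chromosome and is the reference the sampled mode is tested against. Trait
ranking counts samples with p ≤ 0.05 (no multiple-testing correction by
default, Benjamini–Hochberg optional) with ties broken by mean p.

## Simulator

`simulate` generates the structures the method assumes, with truth tables
sufficient to score every downstream operation:

* **Bulk reads**: well-separated 4-CpG segments; each read draws a cell
  subset from the segment's mixing proportion (uniform in 0.3–0.7), CpG
  states Bernoulli with subset probability 0.95/0.05 at CSM segments and a
  shared 0.5 at uniform segments; 20× depth; conversion failures flip U→M
  at 0.003 (a 99.7% conversion rate); duplicates re-emit existing reads
  under fresh ids. Segment layout guarantees each read covers exactly one
  segment, so classifier tests are not confounded by window effects; the
  denser-map path is exercised separately in the extraction tests.
* **Hairpin pairs**: molecules of 50–100 bp with CpGs at 5% density; the
  top strand draws one state per molecule by default (somatic methylation
  is bimodal and strongly correlated between neighboring CpGs), the bottom
  strand flips each dyad independently at the asymmetry rate (default
  0.05). Read-through into the loop adapter and sequencing adapter is
  emitted and must be trimmed. Spike-in molecules are fully unmethylated.
  Under molecule-level top states the asymmetric window fraction is
  (asymmetry)^w exactly, which the tests exploit.
* **SNP tables**: null traits uniform over the genome; enriched traits
  place a configured fraction of SNPs inside regions.

Permutation calibration uses 200 null traits of 1,000 SNPs against 100
regions of 200 bp on a 1 Mb chromosome with 1,000 iterations. The SNP count
is set so the overlap-count distribution has wide support: with few SNPs
the permutation p is heavily discrete and a Kolmogorov–Smirnov uniformity
check measures tie mass rather than miscalibration.

What the simulator does **not** emulate: sequencing base-call errors,
indels, mapping ambiguity, PCR bias beyond a flat duplicate rate, realistic
CpG spatial clustering (islands are planted annotation, not sequence
composition), linkage structure among SNPs (proxy expansion is consumed as
input, never computed), or more than two cell subsets. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated generative assumptions, not robustness to alignment artifacts or
complex mixtures.

## Problem sizes and runtime

The test suite and acceptance script run the classifier on 1,000 segments
at 20× (a few tens of seconds), 2,000 hairpin molecules, 100 alignment
oracle pairs, 20 constructed down-sampling clusters × 100 repeats, and the
calibration above — sizes at which every Monte-Carlo tolerance in the tests
is a 3-standard-error band around a closed-form expectation.

## Known limitations

* The Gibbs sampler is exchangeable over reads but, like any finite MCMC
  run, approximates the posterior; the majority vote makes label noise
  negligible at depth ≤ 500 but extremely marginal clusters near the
  weight floor can flip between seeds.
* Depth counted as "reads covering all four CpGs" is stricter than
  "reads covering any CpG of the segment"; segment-level frequencies are
  therefore conservative relative to the looser reading.
* Arm identity uses alignment columns after overhang trimming; very short
  overlaps (arms shorter than ~10 bp after trimming) can pass the 90% gate
  on little evidence. The simulator does not produce such pairs; real data
  should be length-filtered upstream.
* `filter_calls` treats chromosome names literally; supply the exclusion
  list matching the assembly's naming scheme.
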