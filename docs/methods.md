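# Methods

This note documents the models behind each stage, the defaults that
matter, what the synthetic data does and does not emulate, and the
numerical choices a maintainer would want spelled out.

## CIM calling

A crosslink-induced mutation is a C→T transition in the reverse-transcribed
tag immediately 3′ of the methylated adenosine. The caller keeps a position
when all clauses hold, with strict inequalities throughout:

* mismatch support *m* > 1;
* 0.01 < *m*/*k* < 0.5, where *k* is the number of unique tags spanning the
  position (deduplication is assumed upstream);
* the reference reads A-then-C in transcript 5′→3′ orientation. On the
  minus strand this means reference G at the site with T one base higher —
  "preceding" is a transcript-space notion, because the motif itself
  (AAACD) is a transcript-space statement.

Pileups are unstranded, so a position could in principle qualify on both
strands; at most one site per strand is emitted, and when transcript
models are supplied a site inside an annotated gene is kept only on the
gene's strand (both strands survive only intergenically). The lower ratio
bound does real work against sequencing error: at error rate ~10⁻³ an
*m* = 2 call needs *k* < 200 to pass 0.01, so deeply covered false
positions are rejected wholesale.

## Differential peak calling

The external differential caller the field uses is reimplemented as a
documented two-track model rather than ported byte-for-byte. Both
libraries are depth-matched by scaling the deeper one down to the
shallower one's total; with pseudocounted scaled counts x₁ (IP) and x₀
(input) the per-position statistic is the generalized likelihood ratio
for two Poisson observations sharing a rate,

  LLR = [x₁ ln(x₁/m) + x₀ ln(x₀/m)] / ln 10,  m = (x₁ + x₀)/2,

set to zero wherever x₁ ≤ x₀. Positions with LLR ≥ 2.0 (a log₁₀ scale
cutoff; the upstream tool publishes no value, so 2.0 is this package's
documented default) form runs, runs separated by ≤ g = 20 nt merge, and
merged runs shorter than l = 120 nt are discarded.

Writer dependence: a wild-type region is *independent* when at least 50%
of its positions also pass the cutoff in the knockout track — an
operationalization of "signal persists in the mutant"; the threshold is a
parameter (`dependence_overlap`). Regions enriched only in the mutant are
emitted as `mutant_only` rather than silently dropped. Peak score is the
mean LLR over the region; the summit is the LLR argmax.

Splitting: within a peak, local maxima of the raw IP coverage are found
(plateaus count once, at their midpoint); between adjacent summits the
peak is cut at the valley minimum when the valley is below
`valley_ratio` = 0.5 of the lower summit. Children inherit the parent's
label and score (their extent changed, not the evidence class), and
children shorter than 30 nt re-merge with the taller neighbor, so the
children always tile the parent exactly.

## Metagene

For each gene the longest mature transcript (ties by transcript id) is
lifted to transcript coordinates, split at the annotated CDS into
5′UTR/CDS/3′UTR, and each segment is rescaled to 200/1000/300 bins by
area-preserving piecewise-constant resampling (each output bin is the
length-weighted mean of the signal over its fractional window). This
preserves uniformity — flat input stays flat after normalization, which
nearest-neighbor sampling would not guarantee — and preserves segment
mass fractions exactly when all segments share one scale factor. The
1500-vector is divided by its sum; transcripts with a missing UTR
annotation or no signal are skipped and counted. Aggregates are plain
means of per-gene vectors; an IP/input ratio profile is emitted alongside
the two library profiles since the order of normalization and scaling is
a presentation choice.

## Target properties

Peaks are annotated by the fixed precedence other → intron → start codon
→ 5′UTR → 3′UTR → CDS, first overlap wins, evaluated against each gene's
longest transcript ("other" = overlapping no transcript span). Note an
interaction worth knowing: because called peaks are one-to-two hundred
nt wide, a 5′UTR peak that reaches the CDS start is labeled
`start_codon`, and clustered 5′UTR sites merge into a single peak while
isolated CDS/3′UTR sites get one peak each — so peak-level category
fractions under-state the site-level 5′UTR bias by construction.

Genes are binned by their number of writer-dependent peaks (none/1/2/3+;
edges configurable). Each non-empty bin is compared, per property,
against a background of genes with no peaks: the background sample is a
seeded concatenation of `n_draws` = 1000 bootstrap resamples of the
no-peak pool at the bin's size, pooled (one ECDF), with the pool sorted
before resampling so results are independent of input row order.

The KS statistic is the exact sup-distance between right-continuous
ECDFs. The p-value uses the asymptotic Kolmogorov distribution with the
Stephens finite-sample argument correction,
(√nₑ + 0.12 + 0.11/√nₑ)·D, and — the one subtlety — the effective size
uses the *pool* size for the background, not the length of the bootstrap
concatenation: the resample carries no information beyond the pool, and
using its nominal length inflates the type-I error to roughly 9%.
With the pool-size convention the measured null rejection rate is
0.04–0.06 at α = 0.05 (200 simulations). No ties correction is applied
(the properties are continuous); raw p-values are reported to match how
such comparisons are usually presented, with Benjamini–Hochberg left to
the caller.

## Behavior

A trial's half PI is the mean over the final 30 s of
0.5·(n_unconditioned − n_conditioned)/n_total per video frame; frames
with no fly in either zone are skipped, not zero-filled. The 0.5 factor
makes the reciprocal pair sum — full PI = half PI(OCT) + half PI(MCH) —
span [−1, +1], and the summation cancels innate odor bias. Effect sizes
are mean differences with a BCa bootstrap CI (5000 resamples by default;
percentile by flag); BCa is slightly anticonservative at n ≈ 14 units
per group (measured coverage ≈ 0.94 for a nominal 0.95). The
Mann–Whitney p is exact by enumeration when both groups have ≤ 8 values
and uses the tie-corrected normal approximation otherwise; it is
reported for legacy comparability, not inference.

Precision planning: the margin of error of a standardized two-group mean
difference at equal n is z₁₋α/₂·√(2/n) (0.33 SD units at n = 72), and
power is the two-sided normal approximation Φ(δ − z) + Φ(−δ − z) with
δ = d·√(n/2), which reduces exactly to α at d = 0; a seeded Monte-Carlo
mode (t or Mann–Whitney test) gives ≈ 85% at n = 72, d = 0.5.

## Probe proteomics

Proteins must be recovered in both replicate pulldown datasets to be
scored (absence from a replicate's table counts as non-recovery). All
counts receive a pseudocount of 1 — applied to everything, not only
single-probe identifications, for continuity of the ratio map — and each
replicate yields log₂((m⁶A + 1)/(A + 1)). Classification uses per-replicate
quartile fences: bound above Q3 + 2×IQR in *both* replicates, repelled
below Q1 − 2×IQR in both, else background; strict inequalities, so a
degenerate all-equal ratio set classifies everything as background. A
pooled-fence mode exists behind a flag since the published description of
the 2×IQR threshold does not fix the axis convention.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analyses rely on:
a 500-gene single-contig transcriptome (mean 5′UTR/CDS/3′UTR lengths
300/1500/400 nt, ±15%, fly-typical; single-exon by default, multi-exon by
flag), 35% of genes methylated with 1–6 sites (heavier loads mimic the
clustered 5′UTR methylation of head m⁶A targets), site segments drawn
0.8/0.1/0.1 for 5′UTR/CDS/3′UTR, and the AAACT context written into the
sequence (configurable, e.g. GGACT, to test context-free behavior).
Writer dependence (80% dependent) is drawn per gene, so IP-enriched
regions are homogeneous in dependence — modeling writer-independent
signal as regional non-specific pulldown rather than a per-site coin
flip.

Coverage is Poisson: depth 30 per mature position in inputs; in IP
libraries a site multiplies the rate by 8 within ±100 nt, decaying
linearly to 1× at ±130 nt (a size-selected-fragment footprint; overlapping
sites combine by maximum). The knockout IP is enriched only at
independent sites. C→T mismatches are Binomial(k, 0.15) at active
crosslink positions and Binomial(k, 0.001) elsewhere, the latter chosen
so the CIM filter's lower ratio bound is genuinely exercised. Property
tables: log2fc ~ N(0, 0.5) and half-life ~ logN(ln 4 h, 0.6) independent
of methylation; log₂ TE reduced by 0.7 per dependent site. Behavior:
each fly is a two-state Markov chain over chamber sides with stationary
probability equal to the group's avoidance bias and switch propensity
0.2 per frame at 5 fps; each unit of 12 flies runs two reciprocal
trials. Spectral counts: per-protein lognormal baselines, Poisson
replicates, planted readers at 8× on the m⁶A probe, and a fraction of
background proteins absent from one replicate to exercise the
consistency filter.

Not emulated: read-level artifacts (PCR duplicates, mapping bias,
alignment error), fragment-length variation, stranded pileups,
overlapping genes, isoform diversity, batch effects between replicates,
and real locomotor dynamics. Passing tests therefore demonstrate that
the *statistical machinery* recovers planted structure under the stated
generative model, not that the pipeline is robust to upstream artifacts
real libraries carry.

## Problem sizes and determinism

The shipped analyses and tests run the full pipeline at 500 genes
(~1.2 Mb contig; the planted-site recovery check uses the 200-gene
configuration at seed 7), 200 null property simulations for calibration,
1000 simulations for CI coverage, and 10,000 replicates for the power
estimate — sizes chosen so the whole suite completes in well under a
minute while leaving the binomial error bars of every calibration check
several times smaller than its tolerance. Every random draw flows from
an explicit seed through `numpy.random.default_rng`; staged generators
derive independent streams from (stage constant, seed) pairs, so any
stage can be re-run in isolation byte-identically.

## Known limitations

* The LLR cutoff (2.0), dependence-overlap rule (50%), and valley ratio
  (0.5) are this package's documented defaults; the upstream tools'
  exact values are unpublished, so absolute peak counts are not
  comparable across implementations, only the qualitative
  dependent/independent split.
* Metagene mass fractions are only exactly conserved for equal segment
  scale factors (by design of mean-resampling).
* The KS p-value treats the bootstrap background as fixed at its pool's
  information content; with very small bins (n ≤ 2) the asymptotic
  distribution is approximate and p-values there should be read
  qualitatively.
* BCa intervals at n ≲ 10 per group undercover; the suite quantifies
  this at n = 14 (≈ 0.94) but smaller designs should use the exact-n
  coverage as measured, not the nominal level.
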