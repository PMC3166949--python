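# Methods

## The analysis problem

In *Saccharomyces cerevisiae*, adding glucose to cells growing on a
gluconeogenic carbon source rewires the transcriptome within minutes.
Much of this response is attributed to protein kinase A (PKA), activated
by the glucose-triggered cAMP spike, but PKA-independent routes exist.
The decisive experiment compares three genotypes: a PKA-proficient
reference (*TPK1 TPK2 TPK3*) and two strains completely devoid of PKA,
kept viable by suppressor mutations (*tpk1 tpk2 tpk3 msn2 msn4* and
*tpk1 tpk2 tpk3 yak1*). Each is profiled on ethanol, 30 minutes after
glucose addition, and during steady exponential growth on
glucose+ethanol, in biological duplicate, with an optional
PKA-activation pseudo-condition (cAMP raised without glucose) available
for the reference genotype. This package implements the analysis of
such a design as a reusable, tested pipeline operating on probe-set
signal matrices.

## Normalization

Each array is globally scaled so its plain mean signal over all gene
features equals a fixed target, 150 signal units by default (the
standard global-scaling convention for this array generation). A
trimmed mean is available (`NormalizationConfig.trim_fraction`) but is
not the default. The pipeline order is fixed — scale each array, then
average biological replicates, then compute factors — which makes all
downstream ratios exactly invariant to per-array loading differences:
multiplying any column by any positive constant changes nothing
downstream. Scaling is idempotent.

Replicate QC computes, per gene and (strain, condition) group, the
relative deviation |x−x̄|/x̄ of each replicate from the group mean;
groups whose mean is zero are skipped and counted, single-replicate
groups are skipped and logged. The reporting threshold is 25%, the
level biological duplicates of this design generally stay within.

One caveat is intrinsic to mean-targeted scaling: if a large fraction
of genes truly responds, the scaling compensation shifts every other
gene slightly in the opposite direction. The fold-change taxonomy is
robust to this (thresholds are 1.8-fold and above, and the 70% rule
compares factors *between strains*, which cancels common shifts), but a
shift-sensitive statistic such as SAM will detect it; the SAM example
demonstrates this deliberately.

## SAM significance for duplicate arrays

For a two-group comparison the per-gene statistic is the relative
difference

    d = (x̄₂ − x̄₁) / (s + s₀),
    s = sqrt( (1/n₁ + 1/n₂)/(n₁+n₂−2) · [Σ(x−x̄₁)² + Σ(x−x̄₂)²] ),

with a fudge factor s₀ that keeps genes with accidentally tiny scatter
from dominating the ranking. s₀ is chosen by the classic
coefficient-of-variation search: candidate values are percentiles of
the s distribution (grid 0, 0.05, …, 1.0); for each candidate the
spread of d (MAD/0.6745) is computed within quantile windows of s
(about 20 genes per window, at most 100 windows) and the candidate
minimizing the coefficient of variation of those spreads wins, ties
toward the smallest percentile. A fixed percentile and the median of s
are available as alternatives.

The null model permutes group labels. All C(n₁+n₂, n₁) relabelings
(identity included) are enumerated whenever their number is at most
`max_enumerated_permutations` (default 1000) — the duplicate design has
only C(4,2)=6 — otherwise that many relabelings are sampled uniformly
with the run's seed. Sorted observed d is paired with the
permutation-averaged order statistics d̄₍ᵢ₎; for a threshold Δ the upper
cutoff is the smallest positive d₍ᵢ₎ with d₍ᵢ₎−d̄₍ᵢ₎ ≥ Δ, the lower
cutoff the largest negative d₍ᵢ₎ with deficit ≥ Δ, and every gene beyond
a cutoff is called. The FDR estimate is the median, over permutations,
of the count of null d values beyond the cutoffs, divided by the number
called (0 when nothing is called; no π₀ correction). When Δ is not
given, the smallest value on an even 60-point grid over
[0, max|d₍ᵢ₎−d̄₍ᵢ₎|] reaching the target FDR (5%) is used. d is computed
on the signal scale by default because the rest of the pipeline is
ratio-based; a log2(signal+1) switch exists.

With only six permutations the FDR estimate is coarse; on
simulated global-null data the median called fraction at the default Δ
stays below 1% across seeds, which is the behaviour the test suite
locks in.

## Response factors and the strength taxonomy

The induction factor of a gene in a strain is the ratio of the
replicate-averaged signal 30 min after glucose to the ethanol baseline
signal; the repression factor is the reciprocal orientation. A strain
is responsive when the factor reaches 1.8-fold. Reporting tiers follow
the conventional bins (induction ≥1.8 and >4; repression ≥1.8, ≥4,
≥15); tiers are bins, not call thresholds.

Denominators are floored at 1 signal unit (configurable) so near-zero
signals cannot blow a ratio up; floored factors carry a flag and by
default do not count as evidence for a "total" call.

Strength of the response in the absence of PKA:

- **total** — at least one PKA-null strain's factor is ≥ 70% of the
  reference factor (a PKA-null factor *above* the reference also
  qualifies);
- **partial** — some PKA-null strain is itself responsive (≥1.8) but
  below the 70% criterion;
- **none** — otherwise.

"Partial" has no published closed-form definition; the rule above is
the minimal one consistent with every published example (ALD5 and GCR1
partial, the ARG genes none).

## The four-class PKA-dependence taxonomy

With three observations per gene — response in the reference strain,
response without PKA (total if either null strain qualifies), and
response upon PKA activation without glucose — genes fall into four
classes:

| class | PKA⁺ + glucose | PKA⁻ + glucose | PKA activated | reading |
|---|---|---|---|---|
| 1 | + | + | − | PKA-independent pathway(s) only |
| 2 | + | − | + | PKA-dependent pathway(s) only |
| 3 | + | + | + | redundant pathways |
| 4 | + | − | − | cooperative pathways |

A partial PKA-null response maps to class 4 (cooperative pathways can
produce partial responses; class 3 requires a full response without
PKA). When the activation condition was not measured, classes 1/3 and
2/4 cannot be separated: a surviving response is reported as class 1
with a flag, a lost one as UNRESOLVED — never guessed.

## Transience

A response is compared between the 30-minute pulse and steady
exponential growth on glucose+ethanol. It is **sustained** when the
growth-condition factor both stays above the sustain threshold
(default: the responsiveness threshold, 1.8) *and* keeps at least half
of the 30-minute factor (`persistence_fraction`, default 0.5);
otherwise, a gene responsive at 30 min is **transient**. The relative
criterion matters: several published marker genes keep growth factors
of 2–3-fold — above any absolute threshold — yet their response has
collapsed from a 10–15-fold pulse and is reported as transient, while a
gene at 5-fold → 3-fold is not. Among the published marker factors the
largest growth/short ratio of a transient gene is 0.36 and the smallest
of a sustained gene is 0.6, so 0.5 separates them cleanly and the calls
are robust to the exact value. Genes below threshold at 30 min but
responsive during growth are **growth-only**.

## Gluconeogenic PKA requirement

Under gluconeogenic growth (ethanol), a gene whose replicate-averaged
signal drops at least `fold` (default 2) in **both** PKA-null strains
relative to the reference requires PKA for full expression; a drop
confined to the *msn2 msn4* (or *yak1*) background instead implicates
that suppressor mutation. Separately, the two suppressor backgrounds
are compared to each other with the same 2-fold rule
(higher-in-msn / higher-in-yak / similar); genes unchanged versus the
reference but divergent between suppressors are reported as
suppressor-divergent. The published tables state no cutoff for
"different expression"; 2-fold is the smallest cutoff consistent with
every printed row's group membership, and it is configurable. All
three calls are invariant under common rescaling of the signals.

## Synthetic data

The generator plants the structures the analysis is designed to detect,
under the study's own conditions:

- **design** — 3 strains × {ethanol, glucose 30 min, glucose growth},
  plus the PKA-activation pseudo-condition in the reference genotype
  only; 2 biological replicates per group.
- **baselines** — log-normal on the signal scale, median 200 units,
  log-sd 0.9 (matching the span of published gluconeogenic signals,
  tens to thousands). Glucose-repressed responsive genes get a
  baseline of at least 100 units: genes repressed by glucose are active
  on a gluconeogenic carbon source, and this keeps their post-repression
  signals above the ratio floor.
- **archetypes** — 10% of genes responsive, split evenly over classes
  1–4 and both directions; effect sizes log-uniform on 4–20-fold
  (a switch pins them for boundary tests); 30% of responsive genes
  transient (effect at 30 min only, reverted during growth); class-4
  genes respond in the PKA-null strains attenuated to a fraction of the
  full effect drawn from [0.1, 0.55] (below the 0.7 criterion by
  construction); 10% of repressed responsive genes are Msn2/4-dependent
  (their ethanol baseline is divided by the effect size in the
  *msn2 msn4* background).
- **noise** — each array gets a log-normal scale factor (loading
  jitter, 30% CV by default) that global scaling must absorb, and each
  measurement log-normal noise with CV 0.12, calibrated so replicate
  deviations generally stay under 25% (observed: ≥99% of groups
  within).

Expected (noiseless) signals are returned alongside, and reproduce the
planted factors exactly. Recovery scoring cross-tabulates planted
against called class, transience and gluconeogenic labels and reports
overall and per-class accuracy.

What the simulator does **not** emulate: probe-level effects,
intensity-dependent (nonlinear) array distortions, correlated noise
between genes, growth-rate differences between strains, and cAMP
kinetics. Passing recovery tests therefore shows that the decision
rules invert the generator's fold-change structure under realistic
noise — not that the pipeline overcomes artifacts real arrays may add.

## Numerical choices and degenerate inputs

- Factors of non-negative signals only; negative values are rejected at
  parse time with the offending gene and sample named.
- Zero denominators are handled by the signal floor; zero-mean QC
  groups are skipped and counted; an all-zero array is a hard
  normalization error.
- SAM: s+s₀ = 0 with equal means gives d = 0 by convention, with
  unequal means it is a degenerate-scatter error; group sizes below 2
  are rejected (factor-only analysis covers single replicates).
- Ties in the s₀ grid search break toward the smallest percentile;
  Δ-selection returns the grid maximum (calling nothing) when no value
  meets the target FDR.
- All stochastic components (simulation, sampled permutations) are
  driven by explicit integer seeds; identical seeds give byte-identical
  outputs.

## Problem sizes used by the test and reproduction scripts

Simulation-backed checks run at the design's full gene count (6000
genes, 20 arrays) for recovery scoring, 500-gene matrices across 20
seeds for the null-behaviour check, and 12–20-gene fixtures for the
exhaustive SAM oracle comparisons, which enumerate every permutation
explicitly.
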