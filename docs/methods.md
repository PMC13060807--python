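# Methods

## Overview

`sigmatch` predicts directed regulatory relationships — gene A supports or
opposes gene B, drug D activates or inhibits gene G — from transcriptomic
perturbation experiments, under the signature-reversion paradigm: a
perturbagen whose expression signature mimics a gene's disruption likely
opposes that gene's function, and one whose signature mirrors the
disruption likely supports it.  The pipeline has five stages: per-sample
z-scoring against matched controls, per-perturbagen consensus signatures,
directional signature matching (DF1), per-pair DEG-threshold selection by
leave-one-out cross-validation, and evaluation/combination of predictors
with smoothed accuracy statistics.  A coexpression-linking stage extends
direct matches to genes whose disruption was never assayed.

## Signatures

**Normalization.** Raw read counts are normalized per sample to
counts-per-million followed by `log2(CPM + 1)`.  This is the
least-surprising convention for comparing samples across studies with
different sequencing depths; samples with zero total depth carry no
information and are dropped.  Pre-normalized (log-scale) input skips this
step.

**Per-sample z-scores.** Each perturbed sample is standardized per gene
against its own study's controls: `z = (x − mean(controls)) / sd(controls)`
with the n−1 standard deviation.  A control standard deviation below
`1e-8` (or undefined, with a single control) is treated as zero: the gene's
z is set to 0 and the gene is flagged rather than producing an infinity.

**Consensus z-of-z.** All samples sharing a perturbagen are collapsed into
one signature.  Per gene, over the n samples that measured it, the
consensus is the one-sample z statistic of the sample z's against zero,
`mean / (sd / sqrt(n))`.  Among the plausible readings of "a z-score of the
z-scores" this one yields a single signed, sample-size-aware value per
gene; dividing by `sd` alone (without `sqrt(n)`) would ignore how many
replicates agree.  Degenerate cases: a gene measured in one sample passes
its z through unchanged; identical z's across n ≥ 2 samples would give an
infinite statistic and are capped at a signed `Z_CAP = 10` (configurable) —
direction is preserved, magnitude is bounded.  The gene universe of a
signature is the union of genes across its samples, each gene using only
the samples that measured it.

**Quality filters.** `target_down_filter` optionally drops gene-disruption
samples whose annotated target gene did not strictly decrease relative to
controls (drug samples always pass); it is a guard against mislabeled or
failed experiments.  `validate_target_direction` reports the concordance
statistic behind that intuition: the smoothed proportion of disruption
samples with the target down, an exact binomial test against 0.5, and a
binomial 95% CI.  Source and species tags are pure metadata filters;
mixing read-count sources is the default.

## The DF1 matching score

At a DEG threshold `T ∈ [0, 1)`, a signature's DEG set is the genes with
`|consensus z| > T` (strict), each carrying the sign of its consensus.
Matching signature A against signature B over their shared measured-gene
universe classifies every gene: STP (shared DEG, same sign), OTP (shared
DEG, opposite signs), FP (DEG in A only), FN (DEG in B only).  Genes
outside the partner's measured universe are dropped rather than counted as
FP/FN, so platform coverage differences do not masquerade as disagreement.

The score components are smoothed precision/recall/F1 pairs:

    SP = STP/(STP+FP+OTP+1)      OP = OTP/(OTP+FP+STP+1)
    SR = STP/(STP+FN+1)          OR = OTP/(OTP+FN+1)
    SF1 = 3·SP·SR/(SP+SR+1)      OF1 = 3·OP·OR/(OP+OR+1)
    DF1 = 2·(SF1−OF1)·|SF1−OF1| / (SF1+OF1+1)

The +1 denominators penalize sparse signatures and keep every ratio
strictly below 1; the quadratic difference penalizes conflicting evidence
in both directions, so perfectly conflicting signatures score 0.  DF1 is
exactly symmetric under swapping A and B when OTP = 0 (the FP↔FN swap then
swaps SP and SR, in which SF1 is symmetric) or when the two DEG sets have
equal size; with opposition and unequal private counts the printed
formulas are mildly asymmetric, and the implementation follows them as
written rather than symmetrizing.

**Direction semantics.** A positive DF1 means the perturbations moved the
transcriptome the same way: for two gene disruptions this implies the
genes support each other (+1); for a drug against a gene disruption it
implies the drug acts like the disruption, i.e. inhibits the gene (−1).
Negative DF1 flips both readings.  Zero carries no direction.

## Threshold selection by LOOCV

No single DEG threshold suits every pair, so `T` is selected per candidate
pair (A → B) from the grid {0.0, 0.1, …, 0.9}.  For each grid value, the
reference relations involving neither A nor any known reference target of
A are scored by DF1; those carrying the requested sign are split into
correct and incorrect by comparing the implied direction with the
reference, and the signed log-rank statistic of correct vs incorrect over
|DF1| ranks the thresholds.  Separate optimizations run for positive and
negative predictions; a pair whose two optima disagree in sign is not
predicted at all (directionality-agreement filter); otherwise the emitted
score is the |DF1| of the optimization whose sign matches.

Numerical choices: a threshold where either group has fewer than two
members receives statistic −∞ and cannot be selected; ties break toward
the smallest T, which uses the largest DEG sets and hence the most data.
The exclusion set is read from the same reference database used for
evaluation, and relations involving B (when B is not a target of A) are
deliberately retained.

## Coexpression linking

Direct matching only reaches genes whose disruption was assayed.  Linking
multiplies the signed DF1 between modifier A and each assayed intermediate
gene B by the Pearson correlation r(B, C) toward every other gene C, and
aggregates the per-intermediate contributions with the same
conflict-penalized quadratic form DF1 itself uses:
`2·(pos−neg)·|pos−neg|/(pos+neg+1)` over the summed positive and negative
contribution magnitudes.  This aggregation is the module's central
surrogate: it mirrors the conflict-penalty shape of the matching score and
is exposed as a pluggable strategy, so an alternative aggregation can be
dropped in without touching the chaining logic.  B = C is excluded (the
direct match already covers it), and optional magnitude floors on |DF1|
and |r| control fan-out.

## Evaluation statistics

All proportion-like metrics are smoothed by incrementing the undesirable
side of the denominator by one.  Unlike Bayes–Laplace smoothing, this
never rewards a small sample: one correct prediction reports accuracy 1/2.
Consequences used by the tests: smoothed metrics strictly undershoot their
raw counterparts whenever the numerator is positive, and converge to the
raw values (the F1 to its own limiting form) as counts scale at fixed
ratio.

**Log-rank prioritization.** A predictor is judged by whether correct
predictions persist to higher scores than incorrect ones as an acceptance
threshold rises.  Scores play the role of fully observed event times; the
statistic is the standard two-group log-rank with grouped-tie
hypergeometric variance, signed so z > 0 when the correct group holds the
higher scores.  Either group smaller than two makes the comparison
meaningless and is flagged rather than computed.  Because directional base
rates are heavily skewed in curated references, evaluation is
sign-stratified: positive and negative predictions are always assessed
separately.

**Binomial machinery.** The exact two-sided binomial test sums every point
mass not exceeding the observed one (`scipy.stats.binomtest`); above
10,000 trials a continuity-corrected normal approximation takes over, and
p-values that underflow are reported as 0.  Confidence intervals use the
inverse binomial CDF at the observed proportion (the spreadsheet
`BINOM.INV` construction), not a Wilson or Clopper–Pearson interval —
matching the convention of the statistics this package reproduces.
Multiple-testing correction is plain Bonferroni, `min(1, p·m)`, with a
configurable hypothesis count (default 72, the number of signature-based
predictor configurations a full benchmark sweep evaluates).

**Accuracy curves and coverage.** An accuracy curve sweeps distinct scores
descending and reports correct/incorrect counts and smoothed accuracy at
each threshold.  The coverage at an accuracy level is the largest correct
count among thresholds achieving at least that level.  Two predictors are
compared by the proportion of A's achieved levels at which B covers
strictly more, with an exact binomial test against 0.5.

## Ensemble

Raw scores are incomparable across predictors, so each is calibrated to an
accuracy estimate â by leave-one-out exclusion: for a query A → B, all
reference relations involving A or B are removed, and the predictor's
smoothed accuracy among remaining reference-covered predictions at scores
≥ s becomes â(s), per direction.  The â assigned to a query is the
*maximum* â among calibration knots at or below its score: every such knot
is a valid accuracy estimate for the query (the query clears that
threshold), and taking the plain topmost knot would punish confident
queries merely because few held-out references score as high — the
smoothing already shrinks thinly supported knots.  The ensemble then
believes whichever predictor reports the highest â, with ties broken by a
fixed configured priority order (default alphabetical) for determinism.
This argmax lets a confidently wrong tool act as a filter on the rarer
direction, a behavior the removal analysis (`loocv_ensemble_evaluate`)
quantifies per predictor as coverage and maximum-accuracy deltas.

## Synthetic data

The generator plants a directed regulatory network and emits every table
the pipeline consumes.  Each ordered gene pair and drug→gene pair carries
an edge with probability `edge_density` (default 0.15, giving each entity
a handful of targets — comparable in coverage, at this scale, to curated
reference sets); half the edges are inhibitory by default; effect sizes
are uniform on [0.5, 1.5] in units of the experiment-level effect scale.
Expression follows a log-normal model: gene baselines ~ N(10, 2) on the
log2 scale, perturbation effects act additively on that scale, and samples
scatter with N(0, noise_sd).  Disrupting gene A pushes A down by
`effect_sd` and each target of A by ±(edge effect × effect_sd) according
to the edge sign; an inhibitory drug reproduces its target's disruption
shift (scaled by the edge effect), an activating drug its negation.  The
coexpression matrix assigns ±strength to network-connected pairs (first
edge wins on conflicting reciprocal pairs) and small Gaussian noise
elsewhere.  One pseudo-random stream per top-level seed with fixed
sub-stream derivation keeps partial regeneration stable.

What the generator does *not* emulate: read-level sequencing noise,
library-composition artifacts, batch and platform effects, correlated
noise between co-regulated genes, indirect cascades deeper than one hop,
and annotation errors.  Null genes have t-distributed consensus values, so
at realistic thresholds DEG sets always contain a noise floor — which is
what makes the planted benchmark non-trivial — but passing tests on this
generator demonstrates correctness of the machinery and recoverability
under the stated model, not performance on real archive-scale data.

**Benchmark sizes.** The recovery benchmark uses five replicate networks
of 30 genes and 10 drugs (seeds 1–5), five perturbed samples and three
controls per study, effect scale 2.0 and noise 0.5.  At this scale a
single replicate yields only ~15–25 reference-covered inhibitory
predictions, too few for a stable rank test, so the benchmark pools the
predictions of all five replicates into one log-rank comparison (pooled
z ≈ 4.9 at these conditions) and additionally checks that every
replicate's own statistic is positive.

## Known limitations

* The consensus reading of "z of z-scores" is one of several defensible
  definitions; it is documented, not asserted as canonical.
* DF1's mild asymmetry under opposition is inherited from the printed
  formulas and left as-is.
* The linking aggregation is a documented surrogate for external
  consensus-combination formulas; linked score magnitudes are therefore
  not comparable to externally published linked scores (directions are).
* Calibration â values are step functions of held-out coverage; no
  isotonic smoothing is applied (a possible extension, off by default).
* Cross-machine bit-reproducibility of floating-point results is not
  assumed; determinism is guaranteed per machine for a fixed seed.
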