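# Methods

`grnbench` builds a fully synthetic two-class expression benchmark with known
biomarkers and evaluates feature-ranking pipelines on it. This note records
the models, the defaults and why, the numerical choices, and what the
synthetic data do and do not emulate.

## Regulatory-network model

Each subject is a gene regulatory network over `p` genes. The signed sparse
weight matrix `W` has `w_ij != 0` iff gene product `j` directly regulates
gene `i`; sign encodes activation/repression, magnitude the strength.
Normalized expression follows saturating relaxation dynamics

    dx_i/dt = beta_i * ( sigma( sum_j w_ij x_j + b_i ) - x_i ),

with the logistic squash `sigma` and per-gene basal input `b_i`. The
normalized fixed point `x* = sigma(W x* + b)` lies in [0, 1] and is
independent of the kinetic rates: `alpha_i` sets the absolute transcript
scale (`alpha_i / beta_i * x_i`) and `beta_i` the relaxation time constant.
All thresholds in the pipeline (hub eligibility 0.88, survival distance) are
applied on the normalized scale, the only scale on which those cutoffs are
coherent. Kinetic rates are drawn hierarchically: population means
`mu_alpha = 20`, `mu_beta = 0.2`; each subject draws its spreads
`sigma_alpha ~ N(0.5, 0.075)`, `sigma_beta ~ N(0.02, 0.0025)` and then
gene-level rates, truncated at a small positive floor.

The steady state is found by damped fixed-point iteration
(`x <- 0.5 x + 0.5 sigma(Wx+b)`), tolerance 1e-8 on the max-norm residual,
at most 2000 iterations; the evolutionary loop solves all offspring of a
generation jointly as one block-diagonal sparse system.

**Topology.** The generator draws out-degrees from a zeta-like distribution
(exponent 2.0) truncated at 15% of the block size and adjusts the total one
unit at a time to hit the requested edge count exactly, so a handful of
regulator hubs emerge without a single gene absorbing the edge budget.
Targets are uniform; weights are N(0, 1). An evolvable subnetwork (the
first `n_sub` genes) is kept disconnected from the background so the
evolutionary operators cannot leak. At reduced scale the edge budget keeps
the full-scale *mean degree* (1619/900 ≈ 1.8 edges per gene) rather than
matrix density, because per-gene degree — not density — determines the
expression distribution and hub structure the disease model depends on.

**Basal input.** `b_i ~ N(0, 2.5)` by default (`bias_sd=0` restores a
symmetric all-0.5 baseline). With zero basal input and mean degree 1.8,
nearly every gene sits at `sigma(0) = 0.5` and almost none exceed the 0.88
hub-eligibility threshold; dispersed basal activity spreads steady states
over the whole [0, 1] range — as observed expression data are spread — and
yields a stable pool of ~20% near-saturated genes from which perturbation
hubs can be drawn at any seed.

## Population evolution

The founder genotype is cloned into M subjects; each generation applies,
inside the evolvable block only:

1. **pairing** — each row of the child's block comes whole from one of two
   uniformly drawn parents (p = 1/2 per row; self-pairing allowed, 1/M);
2. **mutation** — every nonzero weight is independently replaced by a fresh
   N(0, 1) draw with probability `0.025 / nnz` (nnz = founder's recorded
   nonzero count), so a subject mutates with probability ≈ 0.025; zero
   entries never mutate and the sparsity pattern is immutable;
3. **selection** — a candidate survives iff the Euclidean distance between
   its steady-state phenotype and the founder reference profile is at most
   theta; the generation is refilled until M survivors exist (retry budget
   50·M).

Theta is calibrated per run as the 99.5th percentile of phenotype distances
of probe mutants — founder copies with exactly one random nonzero weight
resampled from N(0, 1), the typical mutation load of a mutated subject at
the default rate (a fixed theta can be supplied for replication). Defaults:
M = 400, 30 generations at the reduced scale; M = 1000, 150 generations at
full scale.

## Disease model and ground truth

Hubs are the k = 6 evolvable genes with the highest out-degree among those
whose founder steady expression exceeds 0.88 (ties: higher expression, then
lower index). Knock-out zeroes row `j` of `W` and clamps `x_j = 0`
persistently (a zeroed row alone would let `sigma(b_j)` re-express the
gene); knock-down halves row `j` and the gene's transcription ceiling, so
its normalized expression is capped at half its unperturbed level. Each
diseased subject carries 4, 5 or 6 affected hubs (equal thirds, remainders
to smaller sizes); per hub, affected subjects split 1/3 knock-out : 2/3
knock-down (remainders to knock-down). Diseased steady states are
recomputed on each subject's own evolved genotype, so the diseased group is
heterogeneous in both genotype and lesion.

Ground-truth biomarkers are the genes reachable from at least one hub in
the regulation digraph (hubs included) whose noise-free steady state moves
by more than epsilon = 0.01 (1% of the dynamic range; configurable) under
some single-hub knock-out or knock-down. Joint, subject-specific
configurations are deliberately not used for the truth set: "modified by
the perturbation" is a per-hub notion, and the union over single-hub
perturbations is subject-independent. At the default reduced scale this
yields truth sets of roughly 50–110 of 2000 genes across seeds — a few
percent of the feature universe, the regime the benchmark is designed for.

## Noise model and study design

Per-gene measurement-error variances are drawn once per cohort from a
lognormal whose *variate* mean and SD are 0.22 and 0.35 (values estimated
from within-group microarray error variances); the log-scale parameters
come from the exact moment identities `sigma^2 = ln(1 + s^2/m^2)`,
`mu = ln(m^2 / sqrt(m^2 + s^2))`. Noise is additive Gaussian,
`N(0, sqrt(v_g))`, identical SD for all samples of a gene, applied on the
normalized expression scale; values are left unclipped by default
(`clip_negative` exposes truncation at 0).

Cohorts (half healthy, half diseased, disjoint subjects) are partitioned
into replicate datasets: within each group-size tier (e.g. 10 datasets of
20/group and 10 of 10/group) datasets are class-balanced and pairwise
disjoint, so between-replicate variation is sampling variation only.

## Ranking pipelines

Four weighting engines produce non-negative per-feature relevances; all of
them, and all downstream classifiers, standardize features with statistics
of the data they are fitted on (gene variances are lognormal-heterogeneous;
unstandardized margins are dominated by the noisiest genes):

* **LSVM** — |hyperplane coefficients| of a linear soft-margin SVM;
* **GSVM** — Gaussian-kernel SVM; per-feature criterion is the kernel-RFE
  margin change when the feature is removed (computed in closed form from
  the fitted dual coefficients);
* **SRDA** — |coefficients| of a ridge-regularized least-squares fit to the
  centered class indicator, solved in the dual (n x n system);
* **I-Relief** — margin-based weights from probabilistic nearest
  hits/misses under a weighted L1 metric with an exponential kernel,
  iterated to a fixed point (tolerance 1e-4, max 100 iterations,
  non-negative, unit sum). Its classifier is a linear SVM.

Hyperparameters are tuned by preliminary stratified 3-fold CV over small
grids (c in {0.1, 1, 10, 100}; bandwidths as multiples {0.25..4} of the
median pairwise training distance; SRDA alpha in {0.01..100}); ties break
toward the strongest regularization (smallest c, largest sigma, largest
alpha). The grid floor of 0.1 for c matters: with p >> n the tuning error
is flat in c, and c = 0.01 is a degenerate underfit once the feature set
shrinks. I-Relief's bandwidth is scored by the error of a linear SVM on
weight-rescaled features, since its own classifier has no bandwidth.

**ERFE.** Recursive elimination with an adaptive step: at each round the
engine is refit on the surviving features; the entropy of the 10-bin
histogram of normalized weights is compared with 0.5·ln(10) — when weights
are concentrated (low entropy) the entire lowest-weight bin is discarded at
once, otherwise the worst 20%. Eliminated features fill the ranking from
the bottom (later-eliminated = better-ranked; within a batch, by weight).
Error curves are evaluated at a geometric ladder of model sizes (powers of
two plus p); the chosen size n* minimizes the error, ties to the smallest
size.

**Single cross-validation mode.** The reported list is fit on the whole
dataset; the error curve is selection-bias-free: within each of 3
stratified folds the engine re-ranks the training part only and per-size
classifiers are scored on the held-out part. The MCC is computed from the
summed held-out confusions at n*. (Ranking once on all data and
cross-validating only the classifier yields curves that are identically ~0
at size 1 here, collapsing n* to 1 — the selection-bias artifact this
design guards against.)

**Bootstrap mode.** B external stratified train/test splits (test fraction
1/3; B = 20 at the reduced scale, 100 at full scale) with tuning and
ranking confined to each training part. Rankings aggregate by mean rank
(ties by mean weight); the error curve is the split-averaged held-out
error; the MCC comes from the summed held-out confusions at n*.

**SAM.** Moderated t statistic `d_i = (mean difference) / (s_i + s0)` with
the fudge constant s0 chosen on a percentile grid {0, 5, …, 100} of the
standard errors to minimize the coefficient of variation of |d| across SE
windows. The null is permutation-based (all distinct label assignments if
fewer than n_perm exist) and pooled across genes, with +1-smoothed
p-values. Selection applies Benjamini–Hochberg to the pooled permutation
p-values at FDR 5%. An estimator that divides the median null exceedance
count at the observed cutoffs by the observed count was evaluated and
rejected: the observed maximum is exchangeable with the per-permutation
maxima, so it "confirms" the top gene in half of all global-null datasets;
BH calibrates (median selections 0 under permuted labels) while retaining
full power on strongly shifted genes.

## List-stability metrics

The distance between two complete rankings is the Canberra distance of
their rank vectors, `sum_i |tau1(i) - tau2(i)| / (tau1(i) + tau2(i))`
(1-based ranks). Top-l partial lists are compared through completions: the
*complete* distance is the mean full distance over all pairs of tail
completions, computed in closed form from per-feature expectations (a
feature unlisted in a list has rank uniform on the tail positions;
completions of the two lists are independent), and verified against
exhaustive enumeration for small universes. The *core* distance subtracts
the contribution of features unlisted in both lists, which depends only on
the list lengths. The stability indicator of a set of lists is the mean
pairwise distance divided by the exact expectation over independent uniform
permutation pairs, `E(p) = (1/p) sum_{a,b} |a-b|/(a+b)` (O(p^2), with the
continuous-limit slope `2 ln 2 - 1` per feature beyond p = 30000):
0 = identical lists, ≈1 = independent random lists, ≈1.4 = the
identity-vs-reversal extreme. Partial-list indicators use the same
normalization constant (the expectation for random partial lists is not
separately normalized; exposed via the distance mode).

Selection quality is precision/recall against the truth set (empty
selections score precision 0, flagged as NaN in benchmark tables so SAM's
empty datasets are excluded from averages) and the area under the
precision–recall curve of the full ranking, accumulated at every cutoff
where recall increases. Classification quality is the Matthews correlation
coefficient, with value 0 when any marginal is degenerate.

## Statistical comparisons

Per group-size tier: Wilcoxon signed-rank between each method and its
bootstrap variant (alpha 0.05); Friedman across the four bootstrap variants
(alpha 0.05) with post-hoc pairwise Wilcoxon at 0.05/6; SAM against the
eight classification pipelines at 0.05/8. Identical paired vectors are
reported as p = 1 (no evidence) rather than NaN.

## Reduced-scale defaults and what they show

The default experiment (p = 2000 genes, 300-gene evolvable subnetwork,
540 evolvable edges, M = 400 subjects, 30 generations, B = 20, 200 SAM
permutations) runs end-to-end on one CPU in a few minutes. M = 400 is the
smallest population whose class pools (200 + 200) can supply ten disjoint
balanced datasets of 20 subjects per group.

What the generator emulates: genotype heterogeneity within a phenotypically
constrained population; heterogeneous multi-hub lesions; gene-wise
heteroscedastic measurement noise; replicate small-sample studies.

What it does not: probe-level artifacts, batch effects, missing values, and
— importantly — the compressed effect sizes of log-intensity microarray
data. On the normalized [0, 1] scale a knocked-out hub (expression > 0.88)
moves by ~0.9 while the noise SD is ~0.47, so a few single genes separate
the classes almost perfectly. Consequences visible in the benchmark:
optimal model sizes and SAM selections are small; SAM's few selections are
nearly always true (precision ~0.95–1.0); and while bootstrap resampling
still dominates single cross-validation in mean precision and list
stability at 10 subjects/group, the magnitude of its precision advantage is
seed-dependent (~1.0–1.6x) rather than a stable 2x. Passing tests therefore
certify the machinery and the direction of the resampling effect, not
effect magnitudes on real microarray scales.

## Known limitations

* The dynamics are a declared stand-in (logistic relaxation); no time
  courses, external stimuli, stochastic transcription or mRNA/protein
  distinction.
* Truth membership is binary at a sharp epsilon; genes just below it count
  as false positives for precision even though they respond weakly.
* The GSVM removal criterion scores features one at a time (no interaction
  between simultaneous removals), the standard kernel-RFE approximation.
* Bootstrap aggregation is mean-rank (Borda); other consensus rules are not
  implemented.
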