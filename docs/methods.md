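# Methods

This note documents the statistical procedures implemented in `epioutlier`,
the defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the toolkit's known limitations.

## Data model and scales

The substrate is a probes × samples matrix of β values (fraction methylated,
in [0, 1]; NaN = missing) with a probe manifest (1-based Illumina-style
positions) and a sample sheet. All interval arithmetic and every BED/bedGraph
export use 0-based half-open coordinates; conversion happens exactly once at
export. Linear modelling uses M-values, M = log₂(β/(1 − β)), computed after
clipping β to [ε, 1 − ε] with ε = 10⁻⁶ (configurable); the clip bounds the
magnitude of boundary M-values at ≈ ±19.9 rather than producing infinities.

## Quality control

Filters run in a fixed order — sample detection filter, probe detection
filter, blocklist, sex inference/mismatch removal, cell-composition outlier
removal, optional batch adjustment — and re-running the pass on its own
output is a fixed point away from threshold knife edges. All "> X %" rules
are strict inequalities: a probe failing detection (p > 0.01) in exactly 10 %
of samples is retained, as is a sample with exactly 1 % failed probes.

**Sex inference.** Signal intensities are unavailable at the β level, so sex
is inferred from X-inactivation structure: the per-sample fraction of chrX
probes with intermediate β (0.25–0.75) is high in females (random XCI) and
low in males (bimodal chrX β). Samples are split at the midpoint of the two
1-D k-means centres of that statistic. With fewer than 20 chrX probes the
inference is refused and the reported sex is used with a warning.

**Cell deconvolution.** Reference-based constrained projection: proportions
w over the six leukocyte types solve min‖β − Rw‖² subject to w ≥ 0,
Σw ≤ 1 (SLSQP on the quadratic program; deterministic). The bundled
reference matrix is synthetic — usable only with cohorts generated against
it; real cohorts need a user-supplied reference panel. Cohort-level outliers
are samples at ≥ Q99 + 2 % or ≤ Q1 − 2 % in at least two of the six types;
percentiles are computed on the post-detection-filter cohort.

**PCA outliers.** The visual review of the first two principal components on
chr1 β values is automated as a robust rule: a sample is flagged when its
PC1 or PC2 score deviates from the cohort median by more than 6 scaled MADs
(configurable). 6 MADs flags only gross artefacts, matching the intent of
manual screening without its irreproducibility.

**Batch adjustment.** Parametric empirical-Bayes location/scale adjustment
of M-values: per-probe standardisation against the pooled design-based mean
and variance, per-batch location (normal prior) and scale (inverse-gamma
prior) effects with method-of-moments hyperparameters, iterative posterior
refinement, back-transformation. Single-batch input is an identity; batches
of one sample are rejected. The nonparametric variant is out of scope.

## Rare outlier DMR detection

Per-probe cutoffs are linear-interpolation quantiles of the cohort β
distribution over non-missing values (minimum 20), ± a 0.15 offset:
autosomes (0.9925, 0.0075), sex chromosomes within one inferred sex
(0.99, 0.01). Cutoffs may leave [0, 1], making that direction unreachable at
such probes. Flags are strict comparisons; missing β never flags.

"Consecutive CpGs" means consecutively assayed manifest probes — a run
breaks at any probe not flagged in the same direction. A maximal run becomes
one DMR when at least one window of 3 consecutive run members spans < 1 kb;
the DMR covers the full run extent, so overlapping qualifying windows of one
run merge naturally. Samples with > 100 autosomal DMRs are excluded in a
single pass, without threshold recomputation (a two-pass mode is available).
Collapsing is single-linkage: two calls link when they share the same
direction and ≥ 50 % of the smaller call's probes; the denominator choice
(smaller probe set) is configurable. Each DMR's effect is reported as the
mean of (sample β − cohort median β) over its probes.

Prioritisation counts three reproducible features — population frequency at
or below the cut (or unknown), gene-proximal annotation (gene body or
promoter within ± 2 kb of a TSS), recurrence in ≥ 2 carriers. Manual
inspection, the fourth feature used in practice, is not modelled.

Small-cohort caveat: with n ≲ 100 samples the extreme quantiles are
partially determined by the outlying value itself, which raises (for hypo)
or lowers (for hyper) the cutoff toward the outlier and costs sensitivity;
the detector is intended for cohorts of roughly 200 samples or more.

## Episignature derivation and MVP classification

Moderated testing follows the standard empirical-Bayes scheme for per-probe
linear models: OLS per probe on [intercept, case, covariates] (covariates =
estimated cell proportions), residual variances shrunk toward a prior via
method-of-moments on log variances using the digamma/trigamma closed forms
(the trigamma inverse by Newton iteration), moderated t with d₀ + d degrees
of freedom, BH adjustment. Probes with missing values fall back to
complete-case OLS per probe. When the moment excess is non-positive, d₀ = ∞
(all variances equal the prior) and the reference distribution is normal.

Probe selection: (1) top 1000 by |mean β difference| × (−log₁₀ adjusted p) —
log base 10; the ranking is base-invariant; ties break by probe id for
determinism; (2) top 200 by max(AUC, 1 − AUC), so hypo- and hypermethylated
probes rank symmetrically (AUC = Mann–Whitney U / n₁n₀ with ties counted
0.5); (3) walk the step-2 ranking, dropping probes with Pearson r > 0.85
against an already-kept probe within cases or within controls. Sex-chromosome
probes are removed before derivation, the standard practice for blood
episignatures (X-inactivation and chrY dosage otherwise dominate).

Classification: linear SVM (C = 1, features = β of the selected probes;
kernel and C configurable); the Platt sigmoid is fitted on out-of-fold
decision values from a seeded 3-fold stratified split rather than on
in-sample decision values, avoiding optimistic calibration. Scores are in
(0, 1) by construction; calls use the > 0.5 / < 0.1 thresholds. A sample must
cover ≥ 95 % of signature probes; the tolerated missing values are imputed
with training control means. Concordance checks: Ward clustering on
Euclidean distance (flag = cases form a pure cluster at the 2-cluster cut)
and classical (Torgerson) MDS to 2 dimensions.

Cross-signature comparison reports shared and direction-concordant probe
counts, and an average-linkage Euclidean tree over per-cohort case-median
vectors on the union of each cohort's top-500 DMPs (all DMPs when fewer),
with each cohort's global mean methylation difference attached to its leaf.
One binary classifier is trained per signature; no multiclass scheme.

Control matching is greedy nearest-neighbour (sex exact, minimal |age
difference|, seeded random tie-breaks, selection without replacement) — a
deliberate simplification of full optimal matching.

## Case–control DMR calling and consensus

**Bump-style array caller.** Probes cluster at gaps > 1 kb; the per-probe
case-control β difference is smoothed with a 3-probe running mean; candidate
bumps are maximal same-sign runs with |smoothed difference| ≥ 0.05 and ≥ 3
probes. Family-wise significance: each bump's area (sum of |smoothed
difference|) is compared with the per-permutation maximum area over B = 1000
random label permutations (B = 200 in the test suite for speed); bumps with
p < 0.05 are reported.

**Kernel-style array caller.** Per-probe Welch t statistics are smoothed
with a Gaussian kernel (sd = λ/2, truncated at λ = 1000 bp). BH-significant
probes group into regions split where consecutive significant CpGs are > λ
apart; regions need ≥ 3 CpGs and |mean Δβ| ≥ 0.05; the region p is a
BH-adjusted Fisher combination of member p-values. Neither array caller
claims byte-level equivalence with any published package; they capture the
published parameters (cutoff, λ, B, minimum CpGs) in transparent form.

**WGBS caller.** CpGs on sex chromosomes are removed. The 10× rule is
applied per (CpG, sample): an under-covered sample's counts are masked and
the CpG is kept while both groups retain pooled coverage ≥ 10× ("mask" mode,
default); a strict mode drops any CpG under-covered in any sample, but with
negative-binomial 30× coverage across ten samples that intersection removes
roughly 40 % of CpGs and fragments real regions, so masking is the default.
Group counts are pooled per CpG and methylation fractions smoothed with a
triangular kernel (500 bp half-width); per-CpG two-proportion z-tests use
the smoothed fractions with kernel-effective sample sizes
n_eff = (Σwc)²/Σw²c. Candidate regions are same-sign runs (gap ≤ 1 kb) of
BH-significant CpGs that also carry |smoothed difference| ≥ 5 % — the delta
condition trims smoothing bleed at region edges — with ≥ 5 CpGs and
unsmoothed pooled |difference| ≥ 5 %. Because the scan selects the most
deviant runs, naive region p-values are badly anticonservative; each
region's raw pooled-count z statistic is instead referred to the
distribution of the genome-wide maximum statistic under 200 random
sample-label permutations, with observed-candidate CpGs masked from the
permutation scans so residual signal does not inflate the null. The region
is reported when its permutation p < 0.01; the stricter-than-0.05 family-wise
level keeps clean genomes call-free in ≈ 99 % of datasets rather than
sitting at the 95 % boundary.

**Consensus.** Calls from two distinct callers intersect when they overlap
by ≥ 50 bp in the same direction; the consensus region is the intersection
span and its difference the mean of the two members'. When one caller
fragments a region, every qualifying pair is reported, deduplicated by
identical span and direction. Signature probes are counted against consensus
DMRs per delta tier (5/10/15/20 %): a probe counts when its position falls
inside a tier-passing DMR of matching direction.

## Annotation and enrichment

CpG context derives shores (0–2 kb) and shelves (2–4 kb) geometrically from
the merged island track — so synthetic genomes work — with precedence
island > shore > shelf; each region's length is partitioned into fractional
coverage of the four contexts (summing to 1), which avoids double-counting a
region spanning several elements. Gene context is strand-aware (promoter
< 1 kb upstream of the TSS, 1–5 kb upstream window, 5'/3' UTRs, exons,
introns; multi-label; intergenic when nothing applies). Random backgrounds
match count and length (uniform on 50–3100 bp; starts uniform within
length-weighted chromosomes; seeded) but not GC or gap content. Enrichment
is region-level (a region is a hit at ≥ 1 bp overlap, configurable) with
two-sided Fisher's exact tests; odds ratios use the Haldane 0.5 correction
when a cell is empty. The goodness-of-fit test between annotation
distributions is Pearson's X² with expectations from background proportions;
zero-expectation categories are pooled with a warning. Fisher's exact p on
discrete tables is conservative (super-uniform under the null), so null
enrichment is validated as "rejection rate at 0.05 not above nominal" rather
than exact uniformity.

## Synthetic data

The generator is a pure function of its configuration (identical bytes for
identical configs). Baseline probe means come from a three-mode Beta mixture
(modes ≈ 0.05/0.5/0.95, concentration 80), mimicking the bimodal-with-
intermediate density of real arrays; measurement noise is Gaussian with
σ = 0.03 on the β scale (clipped to [0, 1]), chosen so that thresholds can be
reasoned about directly on β. Batch shifts are additive on β; cell mixtures
(Dirichlet weights, roughly blood-like concentrations) overwrite designated
reference probes; male chrX is bimodal near 0/1, female chrX intermediate,
and chrY is missing in females. Rare-event spikes are runs of 3–8
consecutive probes within 1 kb at |Δβ| = 0.35 by default, placed only where
one direction is feasible for every probe of the run (a probe with baseline
0.95 cannot move +0.35); episignature spikes shift 150 random
intermediate-β autosomal probes by ±0.12 in cases. WGBS tables use
negative-binomial coverage (mean 30, dispersion 5 — coefficient of variation
≈ 0.5, typical of real WGBS) over ~1 CpG per 100 bp (the genome-wide CpG
density; 500 CpGs per 50 kb replicate genome) with 2 spiked 10-CpG DMRs per
genome at Δ = 0.20, and binomial methylated counts.

What it does not emulate: probe-level technical artefacts (dye bias, type
I/II chemistry), co-methylation/LD structure beyond within-spike
correlation, population stratification, age effects on methylation, and
between-sample biological dispersion in WGBS (counts are binomial given the
group fraction). Passing tests therefore demonstrate correctness of the
algorithms under controlled conditions, not field performance on real
cohorts.

## Problem sizes in the test suite

The suite exercises the documented study conditions at sizes a workstation
handles comfortably: probe selection on 50k probes with 29/58 samples;
outlier recovery on 20k probes × 200 samples over three seeds; WGBS recovery
and null discipline over 20 seeded replicate genomes of 50 kb; array-caller
permutation tests at B = 200. Full-scale defaults (B = 1000, 850k probes)
are unchanged in the library.

## Known limitations

- The outlier-DMR quantile thresholds assume a mostly healthy cohort; a
  shared epivariant segregating in many samples inflates its own threshold.
- The WGBS caller's pooled-count model ignores biological replicate
  dispersion; with few, heterogeneous samples its permutation calibration is
  coarse (p granularity 1/(B+1)).
- The synthetic cell-reference panel is not a published reference; estimated
  proportions on real data require a real panel.
- bigWig export is replaced by plain-text bedGraph; no binary track formats
  are written.
- The interactive visualisation layer of the original workflow is out of
  scope; outputs are TSV/BED/bedGraph and JSON.
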