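# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that make results
reproducible.

## Study design and data model

The package targets two-group (UC vs CTRL) multi-omic stool studies with
three blocks sharing one cohort: bacterial and fungal amplicon count tables
(features × samples, non-negative integers, uneven sequencing depth) and a
metabolite concentration table (mg/kg, continuous). Upstream read
processing (denoising, chimera removal, taxonomy) is out of scope; tables
enter already collapsed to whatever rank the user chose. Sample order is
taken from the metadata file — a single authoritative ordering that all
blocks are aligned to by intersection, preventing silent column
permutations.

## Preprocessing

**Feature filters.** A feature is retained when its prevalence (fraction of
samples with a positive value) reaches the omic's threshold, or — for
bacteria — when its mean relative abundance reaches 1%. Defaults: bacteria
25% prevalence OR 1% abundance; fungi 25% prevalence; metabolites 10%
prevalence. The OR reflects that removal requires *both* rarity conditions
for bacteria.

**Rarefaction** subsamples each sample without replacement (multivariate
hypergeometric) to a common depth; the default depth is the smallest
per-sample total after filtering, and shallower samples are dropped with a
warning. Used only for diversity analyses.

**CSS.** Sample *j* is scaled by `s_j`, the sum of its counts at or below
the `q`-quantile of its positive counts (linear/type-7 interpolation —
stated because quantile dialects change `s_j`), times a constant (1000).
The quantile is fixed at 0.5 by default: the adaptive quantile selection of
the reference CSS method is unstable on tables with tens of features, so it
is offered behind `quantile=None` as a documented approximation
(`css_adaptive_quantile`). `quantile=1` degenerates to total-sum scaling,
which the tests use as a limit check.

**Log transform.** Latent-variable models fit taxa on `log2(1 + CSS)`.
Count-derived abundances span orders of magnitude across features; on the
raw scale PLS weights are dominated by the few most abundant taxa and
moderately abundant differential features are invisible. The log puts
multiplicative group effects on a common additive scale. Metabolite
concentrations are instead autoscaled (unit variance) inside the latent
models, the usual metabolomics convention.

**Frobenius normalization** divides a whole block by its Frobenius norm
before multiblock integration, equalizing total block scale across omics
measured in different units. Blocks are centered *after* this normalization
(the order changes the norm, so it is fixed and documented). A consequence,
asserted in tests: every multiblock model is invariant to multiplying any
raw input block by a positive scalar.

## Diversity

Shannon–Wiener `H = −Σ p log₂ p` (base 2 by default, configurable) on
rarefied counts; group difference by two-sided Mann–Whitney. Bray–Curtis
`d(x,y) = Σ|x−y| / Σ(x+y)` on relative abundances. PERMANOVA uses the
sums-of-squares formulation on squared distances, pseudo-F =
`(SSA/(a−1))/(SSW/(n−a))`, with `p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)`
under seeded label permutation (999 permutations by default; the floor is
therefore p = 0.001, and a permutation that happens to recreate the observed
partition counts as an exceedance). The intragroup-distance test pools all
within-group pairwise distances per group and compares the two pools by
Mann–Whitney; pairs sharing a sample are dependent, so this p-value is
indicative — a caveat the function logs.

## Differential analysis

Mann–Whitney per feature (exact null for small tie-free samples, normal
approximation with tie correction otherwise), BH-FDR within each omic
separately (each omic is screened independently before fusion; a global
option exists), and `log2FC = log2((mean_case + ε)/(mean_control + ε))`
with ε = half the smallest positive value in the table, keeping fold
changes finite for features absent from one group.

The LDA effect-size screen follows the familiar staging: (1) per-feature
Kruskal–Wallis gate at BH-adjusted 0.05; (2) survivors rescaled to 10⁶ per
sample; (3) 30 bootstrap rounds subsampling ⅔ of each class and fitting a
one-discriminant LDA with ridge-regularized within-class scatter, effect =
|class-mean difference + discriminant-projected difference|/2; (4) score =
sign · log₁₀(1 + mean effect), threshold 2.0. All knobs are exposed
(`LefseParams`). Scores for case-enriched features are negative (the
figure convention); the enriched group is also stored explicitly so no
consumer needs to parse signs. Bootstrap subsamples are drawn in an order
fixed by the sample partition rather than the label names, which makes
label swapping flip every score exactly. Input columns are renormalized to
sum 1 on entry, making scores invariant to per-sample rescaling.

The confounder screen tests each metadata covariate per omic: categorical
covariates through the LDA screen; continuous ones (age) dichotomized at
the median and additionally tested by PERMANOVA on Bray–Curtis distances.
A covariate is flagged when any omic shows FDR-significant features or a
PERMANOVA p below 0.05.

## Latent models and marker fusion

PCA is the SVD of the column-centered matrix. PLS-DA is NIPALS PLS1 on
`y ∈ {0,1}` (single-column coding; the resulting RMSE magnitudes live on
the unit interval, matching how such models are usually reported; one-hot
is available). VIP uses the first two components by default regardless of
the CV-optimal count, matching the screening convention of two-axis latent
plots; `Σ VIP² = p` is asserted for every fitted model. Cross-validation is
stratified 7-fold (seed recorded): R² and RMSE on the full fit,
Q² = 1 − PRESS/TSS with PRESS accumulated over held-out folds. AUROC is
the tie-corrected Mann–Whitney statistic normalized by `n₁n₀`, computed on
*training* scores — near-1 values are optimistic by construction and the
report says so. If `Xᵀy` is numerically zero the PLS keeps one null
component (zero loadings, prediction = mean), so no-signal data yields
R² = 0 rather than an error.

Fusion: a feature is a case marker iff `VIP > 1` AND `q < 0.05` AND
`log2FC > 0` (control marker with negative fold change). Thresholds are
arguments.

## Multiblock integration

ComDim/CCSWA: per dimension, alternate the dominant unit eigenvector `q` of
`Σ_b λ_b W_b` (`W_b = X_bX_bᵀ`) with `λ_b = qᵀW_bq` from `λ_b = 1`, until
the salience change drops below 1e-10 (max 1000 iterations; full symmetric
eigendecomposition — cohorts are at most a few hundred samples); then
project `W_b ← (I−qqᵀ)W_b(I−qqᵀ)`. At the fixed point the dominant
eigenvalue of the weighted sum equals `Σ_b λ_b²` — the identity the tests
assert (at 1e-6). Dimensions are reported in decreasing total salience.

MBPCA is consensus PCA by the NIPALS super-score iteration; the unit-norm
block-weight vector apportions each super component among blocks. MBPLS-DA
fits the PLS-DA on the column-wise concatenation of the blocks — the
"joined single matrix" formulation, equivalent to super-score-deflated
MB-PLS — and decomposes the super weights into per-block scores
`t_b = X_b w_b` and importances `‖w_b‖²` (summing to 1 per component).
Two dimensions/components by default, matching two-axis exploration.

## Interkingdom networks

Spearman ρ (midranks) for every bacterium × fungus pair on relative
abundances, two-sided p from `t = ρ√((n−2)/(1−ρ²))`; `|ρ| = 1` gets p = 0
(an exactly monotone pair at n ≥ 5). Edges kept at raw p < 0.05 — the
published convention for these networks — with BH correction behind a flag;
constant features are skipped with a log note. Nodes are endpoints of
retained edges only. Metrics: relative connectedness `E/N`, average degree
`2E/N`, and `avg_neighbors_plus_self = 2E/N + 1`. The self-inclusive
convention is adopted because it reproduces *both* published example
networks' printed neighbor counts exactly (8 nodes/5 edges → 2.25;
63/82 → 3.60) while the conventional degree does not; the conventional
value is always emitted alongside so the quirk is never silent. Whether the
original tool counted self-loops is not documented — the choice here is
empirical.

## Synthetic generator

Per omic, feature *i* has log-normal abundance `exp(μ_i + σ_i z_ij)` with
`μ_i ~ N(0, 1.5)` and σ = 1. Planted markers (defaults 20/6/12 per omic,
mirroring the scale of published marker lists, alternating enrichment
direction so compositional totals stay balanced between groups) are
multiplied by `effect_size` (default 4) in their group. Count blocks are
multinomial draws at a per-sample depth uniform on 5,000–50,000 — enough
depth heterogeneity to exercise CSS and rarefaction without overdispersion
machinery. Metabolites keep the continuous abundances. Metadata emulates
the cohort: 53 UC / 37 CTRL, age ≈ N(40.5, 14.1) vs N(50.7, 14.8), ~47%
male, UC-only therapy flags at realistic rates.

Planted bacterium–fungus pairs are coupled by a Gaussian copula: Pearson
`r = 2 sin(π ρ_s/6)` on the latent normals gives rank correlation `ρ_s`
(default 0.8), and ranks survive the monotone exp map. Two observation
effects attenuate what is measurable: compositional closure (the block-sum
denominator injects shared noise, strongest in the 50-feature fungal
block) and multinomial counting. Planted-edge features therefore get a
larger log-mean (+1) and wider spread (σ = 2), after which the observed
Spearman on relative abundances averages ≈ 0.72 for a 0.8 target — inside
the generator's stated ±0.1 calibration band; the residual shortfall is
intrinsic to compositional data, not a copula defect. The seed feeds a
hierarchical stream (one substream per omic, plus copula and metadata), so
enlarging one omic leaves the others bit-identical.

What the generator does **not** emulate: phylogenetic correlation among
taxa, batch effects, overdispersion beyond log-normal×multinomial,
longitudinal structure, and metabolite detection-limit censoring. Passing
tests therefore demonstrate correctness of the statistical machinery under
a clean compositional model, not robustness to those real-data features.

## Problem sizes and determinism

Simulation-based checks run at the cohort scale the package is designed
for (53/37 samples) where the claim concerns that design (marker
recovery), and at reduced scale (20–40 samples, 15–25 features) for
calibration loops repeated hundreds of times (PERMANOVA type-I, null Q²,
salience dominance) — sizes chosen so the whole suite runs on a laptop
core in minutes. Every stochastic step (rarefaction, permutations, CV
folds, bootstrap, generator) is seeded; the pipeline derives per-stage
seeds from one global seed via a spawned seed sequence, and reports are
JSON with sorted keys and no timestamps, so identical config + seed gives
byte-identical output.

## Known limitations

* Network inference ignores compositionality (no SparCC/SPIEC-EASI-style
  correction) — matching the method being reproduced, not best practice.
* Training-fit AUROC overstates generalization; use Q² for predictive
  claims.
* The intragroup-distance test treats dependent pairs as exchangeable.
* LDA effect sizes depend on scatter regularization and bootstrap
  geometry; defaults follow the reference implementation but are not
  bit-compatible with it.
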