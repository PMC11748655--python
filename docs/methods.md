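# Methods

This note documents the statistical model behind glycodacomp, the defaults
and why they are set where they are, what the synthetic-data generator does
and does not emulate, and the numerical choices a maintainer should know.

## Why compositional analysis

A comparative glycomics measurement reports each glycan as a percent of the
total glycan-derived ion intensity of its sample. The K percentages of one
sample are not K free numbers but a point on the (K−1)-simplex: information
about absolute quantity is destroyed by the closure to 100%. Two
consequences drive everything in this package:

1. *Spurious anticorrelation.* If one glycan rises in absolute terms, every
   other glycan's relative abundance must fall. Per-feature tests on raw
   percentages therefore flag unperturbed features, and — because the bias
   is systematic — they do so *more* often as the sample size grows.
2. *Scale ambiguity.* Even log-ratio methods cannot recover the absolute
   scale; a relative decrease may be an absolute increase when the total
   number of molecules differs between conditions.

The package addresses (1) with log-ratio transforms and (2) with a scale
model on the per-sample normalization term.

## Transforms and scale models

Let x·s be a strictly positive sample (preprocessing guarantees this).

* CLR: `x'[g,s] = log2 x[g,s] − log2 gm(x·s) + δ_s`, with the geometric
  mean over positive entries.
* ALR: `x'[g,s] = log2 x[g,s] − log2 x[r,s] + δ_s` for a reference glycan
  r, whose row is removed from the output.

δ_s is one draw per sample (scale is a per-sample property):

| scale model | δ_s | meaning of γ |
|---|---|---|
| none | 0 | — |
| uncertainty | Normal(0, γ²) | breadth of belief about scale differences |
| informed | Normal(log2 ζ_group(s), γ²) | experimental error of the measured scale |

γ defaults to 0.1 (log2 units) everywhere, so every analysis carries at
least some scale uncertainty; γ = 0 recovers the plain transforms exactly.
The draw is implemented additively on the log2 scale: a notation like
"log2(N(ζ, γ))" is ill-defined for non-positive draws, while the additive
reading preserves the stated variance γ² and the normal-centered-on-log-gm
description of the CLR case. The sign convention is that the draw is
*subtracted from the normalization term*, so a group with measured scale
factor ζ = 2 (twice the total material) is shifted **up** by one log2 unit —
this is what lets an informed model turn an apparent relative decrease into
the absolute increase it actually is. ζ is computed as the mean of
per-sample summed ion intensities per group, expressed as ratios to the
lowest-scale group (min ζ = 1); it is only meaningful when equal amounts of
starting material were analyzed per sample.

### ALR reference selection

Each candidate reference r is scored by
`procrustes_corr(ALR_r, CLR) / max(var(log2 x_r), 1e-12)`: a good reference
reproduces the CLR sample geometry and is itself stable. The Procrustes
correlation is computed on samples-as-points configurations: the CLR matrix
(samples × features) is column-centered and projected onto its first K−1
principal components (zero-padded when the rank is lower) so its shape
matches the ALR configuration; scipy's orthogonal Procrustes gives the
residual M², and the correlation is √(1 − M²). The projection is one of
several reasonable constructions for the dimension mismatch; it is logged
in the transform provenance so alternatives can be compared. In `auto`
mode ALR is attempted for N-glycan tables with more than 50 structures and
accepted when the best reference has correlation ≥ 0.9 and log2 variance
≤ 0.1; otherwise the workflow falls back to CLR. Forcing ALR bypasses the
thresholds. The reference variance is computed across all samples
(per-group means are available as an option).

## Preprocessing

Fixed order: collapse duplicate feature ids (mean) → drop features that are
zero/missing everywhere → Winsorize each feature to its [5%, 95%] percentile
range across all samples (linear interpolation; per-group stratification is
available but not default) → structural-zero policy → imputation →
renormalize each sample to 100.

The zero policy distinguishes three cases. An empty/NA input cell is
*missing*. A zero in a feature whose entire group is zero is *structural*
(the glycan is genuinely absent there) and is replaced by a small constant
(10⁻⁵) exempt from imputation, keeping the log-ratios defined while leaving
the signal of absence intact. Any other zero is treated as
missing-at-random and imputed together with the missing cells by iterative
random-forest regression (MissForest scheme: median initialization, each
feature regressed on all others, ≤ 5 iterations or relative change < 10⁻³;
100 trees by default, deterministic for a fixed seed).

After transformation, features with variance < 0.02 on the percent scale
are excluded from testing (the threshold is exposed: the figure "2% overall
variance" can also be read as a fraction of total variance, and a user can
set either).

Motif-level analysis multiplies the relative table by a user-supplied
motif × feature occurrence-count matrix (so a motif appearing twice in a
glycan receives twice its abundance), collapses motifs with identical
abundance profiles to the one with the largest total count (ties broken
lexicographically), and then transforms the motif table like any other.
Aggregation happens on the simplex scale because count-weighted sums are
only meaningful there; aggregating after transformation is available
behind a flag for comparison.

## Testing machinery

Per feature, the transformed values are compared with a two-tailed Welch's
t-test (or paired t-test), with Cohen's d (pooled SD) or d_z as effect
size, Levene's test for heteroscedasticity, and a TOST equivalence test
with default bounds of ±0.5 log2 units on the transformed scale (the bound
is a design choice — no canonical value exists — and is configurable).

Multiple testing uses the two-stage Benjamini–Krieger–Yekutieli step-up
(stage 1 at α/(1+α) estimates the number of true nulls m0; stage 2 reruns
the step-up with m0). Being adaptive, its adjusted p-values can drop below
the raw ones when most hypotheses are non-null; the invariant p_adj ≥ p
holds only for the non-adaptive corrections. A *grouped* variant applies
the correction within user-supplied biosynthetic families, but only when
the grouping is confirmed: the intra-group correlation — the ICC of a
random-intercept model on per-feature-standardized transformed values,
with group × sample cells as the grouping factor — must exceed three times
the inter-group correlation (mean cross-family pairwise r) and 0.1. If
more than 90% of features come out significant, a transform problem is
assumed and the raw p-values are re-corrected with Bonferroni.

Significance is called at a sample-size-aware threshold
`get_alphaN(n) = 2·Φ̄(√(2 ln BF + ½ ln n))` with Bayes-factor threshold
BF = 3: the two-sided tail probability of the z value at which a
Jeffreys/BIC-style approximate Bayes factor against the null (with √n as
the effective sample size) reaches BF. It declines slowly — 0.072 at
n = 8, 0.048 at n = 31, 0.036 at n = 80 — so significant calls always
carry at least the requested evidence.

Multi-group designs use per-feature one-way ANOVA with Tukey HSD
post-hocs; multivariate comparisons use Hotelling's T² with the
Mahalanobis distance as effect size (pseudo-inverse with a flag when the
pooled covariance is singular); time series use OLS of the transformed
feature on time with the regression F-test.

## Diversity, cross-correlation, meta-analysis, ROC

Alpha diversity operates on relative abundances: richness counts features
above 10⁻⁴ percent (so structural-zero placeholders at 10⁻⁵ never count as
expressed), Shannon entropy uses the natural log, and "Simpson" is the
Gini–Simpson index 1 − Σp² (the complement Σp² is available, as the variant
is not standardized in the field). Beta diversity is the Aitchison
distance — Euclidean distance of the transformed profiles, CLR by default
so distances are comparable across analyses — tested with ANOSIM (rank
contrast R) and PERMANOVA (pseudo-F from the sums of squared distances),
both with 999 seeded label permutations and the (1+hits)/(1+perms)
p-value convention, so p ≥ 1/1000.

Cross-class correlation transforms both datasets independently (partner
omics data are treated as compositional too, which is the defensible
default for sequencing-derived abundances; z-scoring is available), aligns
shared samples by sorted id, computes Spearman's rho for every feature
pair with average ranks for ties, tests with t = rho·√((n−2)/(1−rho²)),
corrects with the two-stage BH across all pairs, and reports
non-significant coefficients as zero.

The fixed-effects meta-analysis combines per-study Cohen's d with
inverse-variance weights, using the normal-approximation sampling variance
var(d) = (n1+n2)/(n1·n2) + d²/(2(n1+n2)) (Hedges' small-sample correction
available behind a flag) and a two-tailed t-test of d_combined/se with
Σnᵢ − 2·(#studies) degrees of freedom. ROC-AUC is pairwise concordance
with half credit for ties, computed on transformed values, oriented so
AUC ≥ 0.5 with the orientation recorded; One-vs-Rest mode repeats the
ranking per class.

## The simulator and what passing its benchmark shows

`simulate_profiles` draws each group from a Dirichlet distribution whose
concentration vector is `concentration_scale × base_profile`, with flagged
features' concentrations multiplied in group 2. Defaults — the study
conditions of every benchmark in this package — are: 40 features, base
profile drawn once from a log-normal(0, 1) and frozen in the package
(emulating the skewed abundance spectrum of a real glycome without
shipping data), 25% of features sialylated (2× up) and a disjoint 25%
fucosylated (0.5× down), concentration scale 500 (moderate sampling
noise). Optional per-group ion-total models (mean, CV) emit the totals the
informed-scale path needs.

The benchmark runs, per group size and replicate, the naive workflow
(Welch's t-tests on raw percentages, BH at α = 0.05) and the CoDA
workflows (CLR/ALR, scale uncertainty γ = 0.1, two-stage BH at the
Bayesian-aware alpha), scoring the false-positive rate on unperturbed and
sensitivity on perturbed features. Under these conditions the naive
workflow's FPR climbs with sample size to above 30% at 40 samples per
group while the CoDA workflows stay near the nominal adjusted alpha with
comparable sensitivity. Two caveats on "near nominal": the two-stage
procedure controls the FDR, so with half the features truly perturbed the
*FPR on nulls* may legitimately sit somewhat above the nominal level
(≈ α·R/m0); and the per-sample geometric-mean noise is shared across
features, so null false positives arrive correlated within a replicate.
At 10 replicates per size the per-size FPR estimate carries a standard
error of a few percentage points; the test suite therefore bounds the
sweep-averaged FPR by 1.5× the sweep-averaged nominal alpha and asserts
the per-size contrasts (naive vs CoDA, CLR vs ALR ordering) qualitatively.

What the simulator does *not* emulate: technical replicate variation,
ionization-efficiency differences between glycans, missingness and
measured zeros (simulated profiles are complete and positive, so the
imputation and zero-policy code paths are validated on constructed
fixtures instead), motif structure, and between-subject covariance beyond
what the Dirichlet induces. Passing the benchmark therefore demonstrates
false-positive control against closure and scale artifacts — the failure
mode the method targets — not robustness to every property of real MS
data.

## Numerical choices and limitations

* Problem sizes in the shipped tests (40 features, ≤ 40 samples per group,
  10 replicates per benchmark cell, 99–999 permutations) were chosen so
  the full suite runs in well under a minute while keeping Monte-Carlo
  error small relative to the asserted contrasts.
* Degenerate inputs are flagged, not hidden: zero-variance t-tests return
  (t = 0, p = 1), paired d_z with zero difference-SD returns ±inf,
  constant-input Levene returns NaN, constant time series return p = 1,
  singular covariances set a `singular` flag.
* The ALR reference score floors the variance at 10⁻¹² so an exactly
  constant candidate wins rather than dividing by zero.
* All stochastic paths (scale draws, imputation forests, permutation
  tests, simulations) are driven by explicit seeds and are bit-reproducible;
  the CLI writes the seeds into each run manifest.
* Known limitations: no Dirichlet-multinomial or Monte-Carlo-instance
  modeling of technical variation; no per-feature mixed-effects or
  longitudinal splines; no phylogenetic/biosynthetic-tree-weighted beta
  diversity; motif membership must be supplied (no motif extraction from
  glycan nomenclature); glycoproteomics data are accepted but the nested
  protein–site–glycoform structure is not modeled.
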