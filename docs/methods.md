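# Methods

This note documents the models implemented in `yloss`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Co-expression networks

**Biweight midcorrelation (bicor).** For a vector x with median m and
median absolute deviation MAD, define u = (x − m)/(9·MAD) and weights
w = (1 − u²)²·1{|u| < 1}; bicor is the correlation of the weighted,
median-centred vectors. `max_p_outliers` (default 0.05) caps the influence
of outliers per tail: if the α- (or 1−α-) quantile of u lies beyond ±1, the
corresponding side of u is rescaled so that at most a fraction α of
observations receives zero weight. With `robust_y = False` (the default,
intended for binary or ordinal traits) the second variable enters
mean-centred with unit weights. Zero MAD with positive variance falls back
to unit weights (logged); zero MAD and zero variance is an undefined
correlation and raises. P-values use the Student-t approximation with
n − 2 df, two-sided, and are reported raw (no multiple-testing correction
in this module). Note a structural property, not a bug: for a sharply
bimodal variable (e.g. the eigengene of a sex-driven module) the robust
weighting necessarily attenuates the correlation relative to Pearson —
the within-cluster MAD treats the opposite cluster as outlying mass.

**Adjacency and TOM.** Networks are unsigned: a_ij = |bicor|^β with
β = 5 (soft threshold; `pick_soft_threshold` reports the scale-free fit
R² — the squared correlation of log10 p(k) against log10 k over ten
equal-width connectivity bins, negated when the slope is positive — and
mean connectivity for a power grid). Topological overlap is
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij) with unit
diagonal; connectivity k excludes the diagonal.

**Consensus.** TOMs from ≥ 2 tissues are made comparable by a power
transform matching their q = 0.95 off-diagonal quantiles to the first
(reference) tissue — exponent log Q_ref / log Q_k, a monotone map — and
combined entrywise by minimum. Module merging in the consensus uses the
maximum eigengene dissimilarity across tissues.

**Tree cut.** Modules come from an average-linkage dendrogram of 1 − TOM.
Maximal subtrees joining below `cut_height` = 0.995 form branches; a branch
splits into its two children when both would meet `min_module_size` = 30
and the merge height sits clearly above the children. The required gap is a
fraction of the branch's height range set by `deep_split` ∈ {0..4} →
{0.40, 0.30, 0.20, 0.10, 0.05}; the default 2 → 0.20 is a mid-level split
sensitivity. Branches smaller than the minimum size dissolve to label 0
(unassigned); labels are ordered by decreasing size. This is a hybrid-style
re-implementation: agreement with any particular reference tree-cut code is
not a design goal — recovery of planted structure is, and is what the tests
measure. All traversal is iterative because noise dendrograms are
chain-like and arbitrarily deep.

**Eigengenes, kME, traits.** A module eigengene is the first principal
component of the standardized member expression across samples, unit
variance, signed to correlate positively with the module mean; a
single-member module yields the standardized member itself. kME(i, M) =
bicor(x_i, E_M) (robust both sides); the module hub is the member with
maximal kME, ties broken by lowest transcript id. Module–trait association
uses bicor with unit-weight traits (binary coded {0,1}, ordered traits by
rank), pairwise-complete observations, with nObs the pairs actually used.

**Tissue specificity.** Every (single-tissue module, consensus module)
pair gets a 2×2 membership table and a two-sided Fisher exact
(hypergeometric) p; a single-tissue module is tissue-specific iff no
consensus module overlaps it at −log10 p ≥ 10. Higher-order preservation
between tissues is D = 1 − mean_{i<j} |cor_A(E_i,E_j) − cor_B(E_i,E_j)|/2.

## Transcript filtering

A transcript is kept if its maximum across samples strictly exceeds the
global median over all matrix cells ("exceed the data-set median in ≥ 1
sample"; the global reading is logged so the per-transcript alternative is
auditable), then if its annotation shows cross-hybridisation class 1, a
non-missing mRNA assignment, and the main probe-set design category. The
median rule runs first; the annotation predicates are order-independent.

## Loss of chromosome Y

**Low-Y calls** operate on the sex-associated module's transcripts. The Y
panel is the seven-gene set (DDX3Y, EIF1AY, KDM5D, RPS4Y1, TXLNGY, USP9Y,
UTY) when present, else all Y-annotated transcripts. Per-transcript
z-scores are referenced to male samples. Two calls combine (both required,
and only male tumours are ever flagged):

* *threshold*: mean Y-panel z ≤ −1.0;
* *branch*: male samples are clustered (average linkage, Euclidean) on
  Y-panel z corrected by each sample's mean z over the module's **non-Y**
  transcripts, and cut in two. The correction cancels the module's shared
  latent component, which otherwise drags whole samples low without any
  Y-specific loss. The lower branch counts as a low-Y branch only if its
  branch-mean corrected score is itself ≤ −1.0 — without this
  "discreteness" gate a forced two-way split of an unstructured cohort
  would always nominate some branch.

A full-cohort dendrogram (both sexes, cohort-referenced z) is returned for
visualisation.

**Depth.** Normalised depth d = reads/(gene length in kb × library size) ×
10⁹. `%LOY = 100·max(0, 1 − median_g d_T(g)/d_N(g))` over captured Y genes
(median for robustness to capture artefacts; mean available via argument).
The estimator is invariant to rescaling all library sizes and converges to
100·f under clonal loss of cell fraction f. The paired depth test pools
per-(gene, patient) percent differences 100·(d_T − d_N)/d_N within a group
and applies the Wilcoxon signed-rank test with a Hodges–Lehmann location
estimate; confidence intervals use the exact signed-rank distribution
(dynamic programming) up to n = 40, then the normal approximation.
Group comparisons of %LOY use a Shapiro–Wilk gate (α = 0.05 per group):
both normal → unpaired t, else Mann–Whitney U.

**Y-index.** Per sample × site, the mean over replicates of
I_Y/I_control; per patient × site, the tumour:normal ratio; per patient,
the grand mean and SD over sites. Incomplete replicate sets are averaged
over what is available and flagged at parse time.

## Methylation

Per-sample summaries are medians of 100·methylated/coverage over autosomal
CpGs with coverage ≥ 5 (threshold configurable; X, Y and MT always
excluded, so chromosome-Y dosage cannot confound the summary). The paired
tumour−normal comparison gates on Shapiro–Wilk normality of the
differences: paired t with a t-based CI, else Wilcoxon signed-rank with a
Hodges–Lehmann estimate and exact CI. The unpaired comparison is
Mann–Whitney with the two-sample HL shift.

**DMR caller** (simplified, single-replicate-capable; deterministic):
counts are pooled within each group per CpG (outer join; missing =
uncovered), smoothed with a coverage-weighted 500-bp moving window, and
tested per CpG by a Wald statistic on the arcsine-square-root scale. The
variance is the binomial term 1/(4·coverage) per group plus an
extra-binomial dispersion estimated by method of moments from the raw
per-CpG between-group differences (the CpG's own level cancels there, so
CpG-to-CpG heterogeneity does not leak in) over CpGs that are not
themselves signal-like, i.e. shrinkage is taken to its chromosome-wide
limit; the dispersion contribution shrinks with the effective window size.
Candidate CpGs need p < 0.001 and |smoothed Δ| > 20 percentage points;
candidates within 1 kb and of common sign merge; region boundaries are
refined by flanking CpGs whose *unsmoothed* difference independently meets
the same criteria (edge CpGs are otherwise diluted by out-of-region
neighbours inside the window); regions must span ≥ 3 CpGs and ≥ 50 bp.
Sign convention: negative = hypomethylated in group 1 (tumours). This
approximates, and is not intended to replicate, shrinkage-based
single-replicate callers; acceptance is planted-region recovery.

**Promoters.** A gene is hypo-/hypermethylated if ≥ 1 DMR of the matching
sign overlaps its 1-kb upstream interval by ≥ 1 bp. BED intervals are
0-based half-open; methylation positions 1-based; the DMR→BED conversion in
`promoter_overlap` and the strand-aware upstream construction in
`io.promoters_from_genes` are the only coordinate-arithmetic sites.

## Survival

Deficiency: among male tumours, expression ≤ mean − 1.5·SD (sample SD,
n − 1; boundary inclusive, with a 1e−12 epsilon against float round-off);
females are never deficient. Under normal data the flagged fraction
converges to Φ(−1.5) ≈ 6.7%.

Cox models are fitted by partial-likelihood maximisation with Efron tie
handling (via lifelines, convergence precision 1e−10, ≤ 100 steps), with
Wald CIs. Categoricals are reference-coded (sex M vs F, histology LUSC vs
LUAD, smoking EX/CS vs NS); stage is an ordered integer by default with a
categorical option; smoking "NR" and missing-stage rows are dropped
(complete case, counts logged). The "outlier" covariate is a single
indicator: 1 for deficient male tumours, 0 for everyone else including
females. |coefficient| > 10 is treated as a monotone partial likelihood
(complete separation) and raises naming the covariate — note that a
two-subject dataset with a binary covariate is always in this regime.
The male-only model uses the same covariates minus sex.

Non-nested model comparison: per-subject log partial-likelihood
contributions l_i = x_i'β − log Σ_{j∈R(t_i)} exp(x_j'β) for events (0 for
censored subjects), and T = (l₁ − l₂)/(√n·ω̂) with ω̂² the sample variance
of the per-subject differences, two-sided normal p. A model compared with
itself returns (0, 1); zero ω̂ with non-zero mean difference raises.

Kaplan–Meier curves use the product-limit estimator with Greenwood
variance (lifelines), per group, with median survival.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
the study's scale: 126 patients / 237 samples (111 paired, 13 tumour-only,
2 normal-only), 65 male tumours, 2000 transcripts. Category sizes and the
male count per category are deterministic given the configuration (largest
remainder allocation), so cohort composition does not drift across seeds;
the seed permutes identities and draws values.

Expression follows a one-factor Gaussian model per module: x = μ + shifts
+ σ(λf + √(1−λ²)ε) with loading λ = `within_module_cor` = 0.7 (expected
within-module correlation λ² = 0.49) and residual scale σ = 0.35 log2
units (typical array replicate noise). The sex module (39 transcripts:
16 Y, 15 X-escape, 8 sex-biased autosomal, mirroring the module's
published composition) adds `sex_effect` = 4 log2 units to Y transcripts
in males and to X-escape transcripts in females (half-effect for the
autosomal members in males). X-escape penetrance varies per female sample
(multiplier N(1, 0.25)): without this within-sex heterogeneity the module
eigengene separates the sexes essentially perfectly and the robust
module–trait correlation is paradoxically *weakened* (see the bicor note
above); with it the association lands in the published 0.7–0.9 range. The
male Y level (baseline 3.2 + 4) clears the global data-set median so the
panel survives the median filter, as expressed genes do on arrays. The
second module's factor is active in normal tissue only — the planted
tissue-specific (tumour-degraded) module. Remaining modules are factor-only
and tissue-shared; everything else is i.i.d. noise, with ~2% of noise
transcripts given non-compliant annotations to exercise the filter.

Low-Y flags are planted on exactly round(`loy_fraction`·male tumours)
tumours (default 0.28·65 = 18). In those samples Y-transcript intensities
are multiplied by (1 − 0.9·f) with f = `loy_cell_fraction` = 0.8 (0.9
acting as a purity-like attenuation) and floored at a background intensity
of 2, i.e. x → log2(2^x·(1 − 0.9f) + 2), because the log of a pure mixture
is unbounded below. Coverage counts are Poisson with Y-gene expectations
scaled by exactly (1 − f) in low-Y tumours (~300 reads/kb at the reference
library size of 3×10⁷, log-normal library variation), making `%LOY` a
consistent estimator of 100·f. Methylation is beta-binomial (concentration
ν = 60, coverage ~Poisson(30)) over a bimodal CpG landscape (80% high
Beta(8,2), 20% low Beta(1,9)) at ~150-bp spacing; low-Y tumours' autosomal
CpG means drop by `methylation_shift`/100 (default 10 points, shifting the
per-sample median by the same amount); planted DMR regions start from a
fixed 0.75 level so their delta is unambiguous. Survival is exponential
(constant baseline hazard, median 36 months — proportional hazards holds
exactly) with linear predictor `log_hr_deficiency`·deficient (default
ln 3.8) plus small age/stage/histology/smoking effects; censoring is
independent exponential tuned to `censor_rate` = 0.5 plus a 120-month
administrative cap.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: probe-level array artefacts and batch effects;
realistic genome coordinates and LD-like correlation beyond ordered
positions; tumour purity and immune-infiltration gradients (LOY is a clean
two-state mixture here); CpG-island structure beyond a bimodal mean
distribution; non-proportional hazards and informative censoring;
annotation errors. Recovery results on these cohorts demonstrate
correctness of the inference chain under its own assumptions, not
robustness to everything real cohorts contain.

## Problem sizes and determinism

The default test and reproduction sizes are the study's own: one
237-sample / 2000-transcript cohort for network and low-Y recovery, 20 Y
genes at ~30× for the depth estimator, a 25-CpG planted DMR at 30×
coverage, and 200 replicates of n = 500 for hazard-ratio CI calibration.
Unit tests use smaller cohorts of identical structure. All randomness
flows from numpy `SeedSequence(seed, stream)` with fixed stream ids per
component; identical configuration and seed give bit-identical cohorts and
byte-identical pipeline output tables (fixed `%.6g` float formatting).
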