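# Methods

`pcaqtl` implements hidden covariate inference for molecular QTL mapping
with principal component analysis, together with the surrounding machinery
needed to use and validate it: phenotype transforms, principled selection
of the number of PCs, an HCP baseline, a nominal-pass linear-regression
QTL engine, factor diagnostics, and a simulation benchmark with ground
truth. This note records the models, the defaults and why they were
chosen, the numerical conventions, and the known limitations.

## The statistical problem

Molecular phenotypes (expression, splicing, or polyadenylation levels;
the matrix `Y`, n samples × p features) are affected by unmeasured
technical and biological variables — batch, ancestry, cell composition —
that confound SNP–phenotype associations and cost power when ignored.
Standard practice is to infer K hidden covariates from `Y` itself and
include them, together with the measured covariates `X1`, in every
per-(gene, SNP) regression

    Y[, j] ~ 1 + dosage_l + X1 + X_inferred .

`pcaqtl` takes the inferred covariates to be top principal components of
`Y`, in two variants:

* **PCA_direct** (recommended default): PCs of the transformed `Y`; any
  known covariate whose unadjusted R² on the PC set is ≥ 0.9 is dropped,
  since the PCs already carry it. Filtering uses *unadjusted* R² —
  the question is raw redundancy, not parsimony-penalized fit.
* **PCA_resid**: PCs of the residuals of `Y` on `[1, X1]`, with all known
  covariates kept. Residuals are re-centered and re-scaled before the
  SVD so that the two variants treat features identically; this is a
  package choice, as pipelines differ on whether to re-scale residuals.

## Data transforms

Three standard phenotype transforms are provided: center/scale each
feature to mean 0, sd 1 (ddof = 1); inverse normal transform (INT)
within each feature; INT within each sample. INT maps average ranks r to
Φ⁻¹((r − 3/8)/(n + 1/4)) — the Blom offset, the common convention in the
rank-based INT literature; any strictly monotone transform of the input
therefore leaves the result unchanged.

## PCA conventions

PCA is computed by SVD of the centered (and, by default, scaled) matrix,
returning at most min(n − 1, p) components with PVE_k = s_k²/Σs². The
sign of each component is fixed so its largest-magnitude loading is
positive, making scores reproducible across linear-algebra backends.
Centering always precedes scaling; scaling uses the n − 1 denominator.

## Choosing K

**Elbow.** Each scree point (k, PVE_k) is scored by its perpendicular
distance to the chord joining the first and last points; K is the
component with the largest distance, smallest index on (tolerance-aware)
ties. On a perfectly linear scree all distances vanish and the rule
returns K = 1; screes must be non-increasing.

**Buja–Eyuboglu (BE) permutation test.** Each column of the transformed
matrix is permuted independently B times (B = 20, α = 0.05 by default,
both configurable); component k is retained when its observed PVE
exceeds the empirical (1 − α) order statistic of its B permuted
counterparts, and K is the length of the initial run of retained
components. The sequential (prefix) stopping rule ensures the selected
components are exactly the top-K PCs consumed downstream. Column-wise
permutation destroys inter-feature correlation while preserving
marginals — the classical parallel-analysis null.

A caveat found while validating the two selectors on synthetic data:
with K_true equal-strength hidden factors, the chord-distance elbow
lands essentially deterministically at the scree corner K_true + 1,
whereas BE selects K_true — so the elbow pick exceeds the BE pick. The
opposite ordering (elbow well below BE) that is familiar from real
expression compendia arises from their long-tailed factor spectra, which
the simulation designs here deliberately do not emulate. Comparisons of
the two selectors on synthetic data should be read with that in mind.

## HCP baseline

Hidden Covariates with Prior infers Z (n × K) by minimizing

    ‖Y − Z B‖² + λ₁‖Z − X1 U‖² + λ₂‖B‖² + λ₃‖U‖² ,

a ridge-penalized version of PCA's minimum-reconstruction-error loss in
which the hidden components are softly coupled to the known covariates.
Each block Z, B, U has a closed-form minimizer given the others, so
cyclic updates (order Z → B → U) decrease the objective monotonically;
convergence is declared when the relative objective change over a sweep
falls below 1e-6 (default). Initialization is deterministic — Z⁰ is the
top-K PC scores of `Y` — so fits are bit-reproducible. Default
λ = (1, 1, 1); the penalties' scale is data-dependent and the defaults
are deliberately neutral, exposed in the API and CLI. As λ₁ → ∞ with
λ₂ = λ₃ = 0, the span of Z collapses into the span of X1 (verified by
principal angles in the tests). λ₁ = 0 with K above rank(Y) leaves the
scale of Z unidentifiable and triggers a warning.

## QTL engine

The nominal pass fits, for every (feature j, SNP l) pair in scope, the
OLS regression of Y[, j] on [1, dosage_l, X] and keeps the dosage
coefficient's estimate, standard error, t statistic, and two-sided
p-value at df = n − (#covariates + 2). Computationally the engine
residualizes `Y` and the dosage matrix on [1, X] once (Frisch–Waugh–
Lovell) and then runs per-pair simple regressions on residuals — the
Matrix eQTL strategy, algebraically identical to the full regression,
which the tests verify against explicit per-pair OLS fits. Consequences
worth noting:

* p-values are invariant to per-column affine maps of the covariates and
  of the response (only non-intercept t-tests are reported);
* exactly collinear covariate columns are pruned (QR with pivoting)
  before the degrees of freedom are counted, so duplicating a covariate
  changes nothing;
* pairs whose in-sample dosage variance (after residualization) is below
  1e-12 are reported with NA statistics and excluded from multiple
  testing.

Benjamini–Hochberg q-values are computed over all emitted finite-p rows
by default (per-feature adjustment is available); ranking metrics use
raw p-values, BH only feeds the power metric and `call_significant`.
Genome-wide permutation-based eGene calling is out of scope.

## Simulation designs

Both designs share exact variance bookkeeping: each gene's phenotype is
a sum of centered components (genetic, covariate, optionally trans, and
noise) individually rescaled so that its ddof-1 sample variance equals
the requested share exactly. This makes the realized per-gene PVE a
testable invariant and removes replicate noise in the effect strength;
the variance of the *sum* still deviates from 1 by the sample
cross-covariances of the components, which cannot all be fixed
simultaneously.

**Genotypes.** Each SNP draws a target MAF from Uniform(0.05, 0.5); the
2n haplotypes carry alleles obtained by thresholding a latent
first-order (AR(1)) Gaussian chain with neighbor correlation `ld_rho`
(default 0.5) at the MAF quantile. This yields tunable neighbor LD with
exactly controlled marginal frequencies — at `ld_rho` 0.9 the median
adjacent dosage correlation exceeds 0.5 at n = 200, and at 0 it
vanishes. Genes occupy disjoint cis blocks whose simulated coordinates
are consistent with a ±1 Mb cis-window lookup.

**Design 2** (the main benchmark, cis-regulation only): per gene, a
configurable number of causal cis SNPs with N(0, 1) effects; known and
hidden covariates are N(0, 1) values shared across genes with per-gene
N(0, 1) loadings. Defaults define the reference cell used throughout the
validation suite: n = 200 samples, p = 500 genes, 50 cis SNPs per gene,
1 causal SNP per gene, 3 hidden covariates and no known ones, genotype
PVE 0.1, covariate PVE 0.4. These values give a realistically confounded
regime — hidden structure explains four times the variance of the cis
signal — while remaining computable in seconds.

**Design 1** (trans-dominated): latent N(0, 1) factors load densely on
all genes; a subset of "hotspot" SNPs each drive one factor (the hotspot
explains half of its factor's variance), so every gene acquires a trans
association with every hotspot. One causal cis SNP per gene and the
covariates fill out the variance; the trans share (default 0.6)
dominates. Truth records cis and trans pairs separately. With no
hotspots and zero trans share the design degenerates to a Design-2-like
data set.

Effect-size and loading distributions are standard normal throughout;
the distribution family and scales are parameters, not hard-coded.
All randomness flows from a single seed through numpy `SeedSequence`
streams.

**What the generator does not emulate:** long-tailed factor spectra,
nonlinear covariate effects, realistic LD beyond first-order decay,
population structure, missing genotypes/phenotypes in the simulated
data, and count-level measurement noise. Passing benchmarks here show
that the inference machinery behaves as designed under linear
confounding — not that PCA resolves every real-data pathology.

## Evaluation metrics

* **AUPRC** over (feature, SNP) pairs ranked by ascending p-value, the
  appropriate summary when true pairs are a small minority. The curve is
  traced over distinct p-value thresholds (ties collapse into one step)
  and the area is the step-wise sum of precision at achieved recall;
  tests verify it against an exhaustive threshold enumeration.
* **Power**: the fraction of true pairs significant under BH FDR 0.05
  (default) or a nominal p threshold; both rules are reported because
  conventions differ.
* **Concordance** between true hidden covariates and inferred
  covariates: the mean adjusted R² (1 − (1 − R²)(N − 1)/(N − k − 1)) of
  each true covariate on the inferred set, the mean adjusted R² of each
  inferred covariate on the true set, and the average of the two. The
  score is invariant to column permutation, sign flips, and any
  invertible linear map of either set; identical sets score exactly 1
  and independent Gaussian sets score about 0.

## Diagnostics

Redundancy among externally inferred factors is quantified by
complete-linkage hierarchical clustering at distance 1 − |cor|, cutting
the tree just below height 1 − threshold so that every within-cluster
pair correlates strictly above the threshold; the cluster count is the
number of distinct factors and is non-decreasing in the threshold.
Factor-to-PC correspondence is summarized by greedily pairing the
(factor, PC) with the largest remaining |cor| and reporting the
reordered |correlation| matrix's diagonal and off-diagonal means with
standard errors. Greedy matching can be suboptimal on adversarial
correlation patterns (the tests construct one); an optimal-assignment
mode (`method="optimal"`, Hungarian algorithm) is available, with greedy
as the default because factors produced by PC-initialized methods are
already near the identity pairing.

## Benchmark harness

`benchmark_grid` crosses any subset of simulation parameters, simulates
`replicates` data sets per cell, runs each configured method (Ideal =
X1 + X2, Unadjusted = X1 only, PCA_direct, PCA_resid, HCP, or an
externally supplied covariate table via `external:<path>`), maps QTLs,
and scores AUPRC, power, and concordance. K defaults to the true number
of hidden covariates; "elbow" and "be" policies are available. HCP
requires a nonempty prior matrix, so in cells without known covariates
the harness supplies a single seeded standard-normal prior column.
Design 1 cells are mapped with the exhaustive all-pairs scope because
their truth includes trans pairs; Design 2 uses the cis scope.

## Numerical choices and degenerate inputs

* Zero-variance features are a hard error under scaling, named in the
  message; zero-variance covariates are dropped by loaders with a
  warning; zero-variance factors make correlation undefined and error.
* Rank-deficient designs: collinear columns are dropped (QR, relative
  tolerance 1e-10) with a warning in `regress_out`, silently in the QTL
  engine where invariance to duplication is the contract.
* Missing phenotype cells are rejected unless mean imputation is
  requested; missing genotypes are always mean-imputed per SNP; SNPs
  below MAF 0.01 (configurable) are dropped at load time.
* Elbow/cluster ties: smallest index wins; cluster cuts are strict at
  the threshold (a pair correlated at exactly the threshold stays
  separate).
* BE quantiles use the `higher` order statistic, the conservative choice
  for small B.

## Problem sizes used in the validation suite

The validation suite and `scripts/acceptance.py` run entirely on
synthetic data at the reference cell (n = 200, p = 500, q = 50; 10
replicates for recovery and ordering checks), 100 × 200 matrices for BE
calibration (50 null + 20 spiked runs), 50 random small instances for
the QTL-engine oracle, and 200 instances for the AUPRC oracle. These
sizes were chosen so the full validation completes in well under a
minute of linear algebra per check while keeping every Monte-Carlo
assertion far from its threshold.
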