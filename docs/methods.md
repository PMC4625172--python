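# Methods

## Local ancestry and its summaries

The primitive datum is the dosage x<sub>ij</sub> ∈ {0,1,2} of
reference-population (African) ancestry for individual j at autosomal locus
i, with a genome map. Missing dosages are not supported: the similarity
estimators have no missing-data rule, so validation rejects anything
outside {0,1,2}. Global ancestry is θ<sub>j</sub> = (1/2N)Σ<sub>i</sub>x<sub>ij</sub>,
locus mean ancestry p<sub>i</sub> = (1/2M)Σ<sub>j</sub>x<sub>ij</sub>.
Panels and phenotype tables are aligned by id intersection, preserving
panel order; dropped ids are logged.

## Ancestral similarity estimators

For a locus subset S (genome, one chromosome, or a single locus — the
granularities of genome partitioning):

- `ibs`: A<sub>jk</sub> = mean over i∈S of 1 − |x<sub>ij</sub>−x<sub>ik</sub>|/2.
  Identity in state is defined per locus; the unweighted multi-locus
  average is this package's extension for parity with the other estimators.
- `centered_scaled` (GRM convention): off-diagonal
  (1/N)Σ (x<sub>ij</sub>−2p<sub>i</sub>)(x<sub>ik</sub>−2p<sub>i</sub>)/(2p<sub>i</sub>(1−p<sub>i</sub>));
  diagonal 1 + (1/N)Σ (x<sub>ij</sub>²−(1+2p<sub>i</sub>)x<sub>ij</sub>+2p<sub>i</sub>²)/(2p<sub>i</sub>(1−p<sub>i</sub>)).
  Loci fixed for one ancestry (p<sub>i</sub> ∈ {0,1}) would divide by zero
  and are excluded, with the count logged; they contribute exactly zero to
  the centered estimator and need no exclusion there.
- `centered`: (1/N)Σ (x<sub>ij</sub>−2p<sub>i</sub>)(x<sub>ik</sub>−2p<sub>i</sub>).
  Preferred default: the 1/2p(1−p) weighting presumes an
  allele-frequency-like (roughly exponential) distribution of p<sub>i</sub>,
  whereas locus mean ancestries are tightly clustered near the admixture
  proportion.

No linkage-disequilibrium pruning is applied: dense local-ancestry calls
tile the genome in tracts, so every segment is already fully covered and
LD corrections devised for genotype GRMs have no analogue here.

## REML variance component

Model: y = Xb + g + e, g ~ N(0, σ²g·A), e ~ N(0, σ²e·I); covariates are
fixed effects inside the REML (not pre-residualized). The likelihood is
restricted to the orthogonal complement of span(X): with C an orthonormal
basis of that complement and C′AC = UDU′, the profiled restricted
log-likelihood is a 1-D function of λ = σ²g/σ²e costing O(n) per
evaluation. The optimum is bracketed on a 65-point logarithmic λ grid over
[10⁻⁶, 10⁶] (truncated when projected eigenvalues are negative so the
covariance stays positive definite) and refined by Brent root-finding on
the analytic profile score to |Δlog-lik| well below 10⁻¹⁰; the boundary
λ = 0 is compared explicitly, so exact-zero estimates are representable
(`boundary` flag). A projected similarity whose eigenvalue spread is below
10⁻⁸ raises a non-identifiability error. The SE of the proportion comes
from the expected information of (σ²g, σ²e) at the optimum via the delta
method.

**Scale of the proportion.** A is rescaled by M/tr(A) before the fit, so
σ²g is the mean modeled genetic variance per individual and
σ²g/(σ²g+σ²e) reads directly as the proportion of phenotypic variance.
This matters for the centered estimator, whose diagonal is ≈ 2p(1−p) ≪ 1;
for the other two estimators the diagonal is already ≈ 1. It is a scalar
reparameterization only — per-locus entries are never re-standardized by
their empirical variance, which would re-weight loci and change the
estimator itself.

Genome partitioning fits one similarity granularity at a time (genome,
chromosome, locus), each a separate single-component fit; a joint
multi-component model is out of scope.

For binary traits analyzed on the observed 0/1 scale, the liability-scale
conversion is h²<sub>liab</sub> = h²<sub>obs</sub>·K(1−K)/z² with K the
(sample) prevalence and z the standard normal density at Φ⁻¹(1−K), clipped
to [0,1] with a warning. For a purely polygenic trait the fraction of
additive genetic variance due to local ancestry is 2·F<sub>ST</sub>·θ(1−θ).

## Admixture mapping

Per locus, OLS of y on [X, x<sub>i</sub>] with a two-sided t-test on the
ancestry coefficient; constant or collinear loci are flagged and skipped.
ΔR² = R²(full) − R²(reduced) is computed from residualized cross-products
(algebraically identical to the two-regression difference). The effective
number of tests treats each chromosome's dosage sequence as AR(1):
ρ̂<sub>c</sub> is the mean cross-individual correlation of adjacent-locus
dosages and the chromosome contributes
max(1, M<sub>c</sub>(1−ρ̂<sub>c</sub>)/(1+ρ̂<sub>c</sub>)), clamped overall
to [number of chromosomes, N]. This form uses exactly the quantity named —
autocorrelation of local ancestry — and recovers both limits (independent
loci → N; perfectly correlated chromosome → 1). Peaks group sub-threshold
loci by chromosome contiguity, a run surviving one (but not two)
consecutive supra-threshold loci; the contiguity rule is this package's
convention.

## Phenotype preprocessing

Quantitative traits: Box-Cox first (λ maximizing the profile
log-likelihood over [−5,5], tolerance 10⁻⁶; non-positive inputs shifted by
−min + 10⁻⁶·range; |λ| < 10⁻⁸ falls back to log), then a single-pass
winsorization at mean ± 3 sample SD with the moments computed once from
the input — no re-estimation loop, so a second pass can move previously
clipped points by a sliver (bounded by a few percent of the SD) as the SD
shrinks. Note a small-sample floor: with n points the largest standardized
deviation is (n−1)/√n, so at n ≤ 10 nothing can ever exceed 3 SDs. Binary
outcomes bypass transformation entirely. Discrete covariates are
dummy-coded dropping a reference level; the design must be full rank.

## Synthetic admixed panels

The generator emulates a two-way admixed population: θ<sub>j</sub> ~ Beta
matched by moments to mean 0.80, SD 0.11 (defaults; `aric_like_config`
gives 0.822/0.103, typical of large African-American cohorts), and per haplotype a
two-state Markov process on a uniform genetic grid — redraw probability
1 − exp(−g·Δ) per interval of Δ Morgans, stationary distribution
(θ<sub>j</sub>, 1−θ<sub>j</sub>) — giving exponential ancestry tracts with
rate g per Morgan. Defaults: 22 chromosomes × 60 loci, 1.5 Morgans per
chromosome, g = 6 generations since admixture. Base-pair positions map the
genetic grid at 1 cM/Mb. All randomness flows from a single seed;
identical configs are bit-identical.

Phenotypes: the single-locus mode returns y = β(x−2p) + e with
e ~ N(0, 1−σ²) and β calibrated so the realized signal variance is exactly
σ² (β = √(σ²/var(x)); under independent ancestry alleles var(x) = 2p(1−p)
and this is the classic σ² = 2p(1−p)β² calibration — in an admixed sample
the spread of θ correlates an individual's two alleles and inflates var(x)
by ~7%, so calibrating on the realized variance keeps the tabulated truth
equal to the realized variance fraction). The polygenic mode draws
u<sub>i</sub> ~ N(0,1) per locus, forms Σu<sub>i</sub>(x<sub>ij</sub>−2p<sub>i</sub>)/√N,
rescales to empirical variance exactly h², and adds N(0, 1−h²) noise.

What the generator does *not* emulate: local-ancestry inference error (real
dosages are themselves estimates), chromosome-specific map lengths and
recombination heterogeneity, assortative mating, selection, genotypes
beneath the tracts, and three-way admixture. Passing tests therefore
establish the estimators' behavior under a clean two-way tract model, not
robustness to inference noise.

## The bias study

For each true variance fraction on the grid (0, 0.005, 0.01, 0.05, 0.10,
0.15, 0.193 — 0.193 being the benchmark major-effect locus size), 100
phenotype replicates are simulated conditional on the panel's causal-locus
dosages and re-estimated by (a) fixed-effects ΔR² at the causal locus and
(b) REML per estimator and partition. Bias is mean(estimate) − truth; the
one-sample Wilcoxon signed-rank test (exact for ≤ 25 non-zero differences,
continuity-corrected normal beyond — the convention under which 100
same-sign differences give p ≈ 3.96×10⁻¹⁸) flags systematic bias.
Estimates are used as returned, including boundary zeros. The generative
model has no covariate effects, so these fits use an intercept-only
design; adding global ancestry as a covariate would absorb the
θ-correlated share of the single-locus signal and distort the truth being
recovered.

The study runs on a synthetic panel at the study scale n = 2600 with
admixture moments 0.822/0.103 (the acceptance tests use exactly this).
Expected patterns at that scale: fixed effects unbiased everywhere
(|bias| < 0.01); both REML estimators slightly positive at zero truth
(boundary inflation); `centered_scaled` increasingly biased downward as
truth grows (≈ −0.03 at 0.193 genome-wide, ≈ −0.16 restricted to the
causal locus) — random effects shrink a large effect toward their finite
prior variance, and partitioning toward the causal locus exacerbates it
because "unrelated" individuals are not unrelated at a shared causal
locus; `centered` shows no downward shrinkage (a small positive offset,
≈ +0.01, is detectable on some panel realizations). At smaller n (≲ 1000)
a small-sample downward drift appears in the genome-wide `centered` fits;
the study is therefore run at full scale. On this generator the `ibs`
genome fits *over*-estimate (the un-centered matrix is dominated by a
large positive offset plus global-ancestry structure, leaving the
informative projected structure on a small eigenvalue scale); the sign of
IBS misestimation is panel-structure dependent and the tests assert
significant, truth-increasing misestimation rather than a direction.

Conditional power simulates complete datasets (dosages as two
Bernoulli(0.822) draws, n = 2600; a locus explaining r² = 0.193; two-sided
test at α = 2.21×10⁻⁴) and reports the detection fraction with an exact
binomial CI — at these settings power is indistinguishable from 100%, so
a locus of that size is not subject to winner's-curse inflation.

## Numerical conventions

Dosage files are tab-separated text (`chrom pos id [cM] ind...`);
similarity matrices round-trip through the lower-triangle GRM text dialect
at 6 decimals (read-back error ≤ 5×10⁻⁷). Positions are 1-based;
chromosome labels sort naturally (1..22). Scan p-values are floored at the
smallest positive double. The Hamming ancestral distance is 2 − (shared
labels) for unordered diploid pairs over any alphabet; the
triangle-embedding distance places the three homozygotes at the vertices
of an equilateral triangle (side 2) with heterozygotes at midpoints and
returns squared Euclidean distances (0/1/3/4) — under that geometry
opposite homozygotes are at distance 4, and the (AA,BC)-type value 3 fixes
the scale.
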