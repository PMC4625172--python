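# admixvar

Phenotypic variance explained by local ancestry in admixed populations.

In an admixed genome — African Americans being the motivating case — each
locus carries 0, 1, or 2 chromosomes from a given ancestral population
(*local ancestry*, x<sub>ij</sub> ∈ {0,1,2}), and each individual has a
genome-wide admixture proportion (*global ancestry*,
θ<sub>j</sub> = (1/2N)Σ<sub>i</sub> x<sub>ij</sub>). `admixvar` asks how
much of a trait's variance local ancestry explains, two complementary ways:

- **Fixed effects (admixture mapping).** Per-locus OLS of the transformed
  phenotype on x<sub>i</sub> plus covariates; the locus's contribution is
  ΔR² = R²(y ~ X + x<sub>i</sub>) − R²(y ~ X). Genome-wide significance
  uses a partial Bonferroni level α/n<sub>eff</sub>, with the effective
  number of tests n<sub>eff</sub> = Σ<sub>c</sub> M<sub>c</sub>(1−ρ̂<sub>c</sub>)/(1+ρ̂<sub>c</sub>)
  from the lag-1 autocorrelation of local ancestry per chromosome.
- **Random effects (variance components).** Single-component REML of
  y = Xb + g + e, g ~ N(0, σ²<sub>g</sub>**A**), where **A** is an
  *ancestral similarity matrix* built from local ancestry by one of three
  estimators: identity in state (`ibs`), centered and scaled by
  2p<sub>i</sub>(1−p<sub>i</sub>) (`centered_scaled`, the GRM convention of
  GCTA), or centered only (`centered`, the GEMMA convention — preferred,
  because locus mean ancestries p<sub>i</sub> are nowhere near the
  exponential-shaped distribution of allele frequencies that motivates the
  scaling). The reported quantity is σ²<sub>g</sub>/(σ²<sub>g</sub>+σ²<sub>e</sub>)
  with a delta-method standard error; binary traits convert to the
  liability scale via h²<sub>liab</sub> = h²<sub>obs</sub>·K(1−K)/z².

The package also includes the supporting theory
(2·F<sub>ST</sub>·θ(1−θ), the fraction of additive genetic variance due to
local ancestry for a purely polygenic trait), multi-way ancestral distance
measures (Hamming / triangle-embedding), Box-Cox + winsorization phenotype
preprocessing, Monte-Carlo conditional power, and a **simulation study of
estimator bias**: random-effects models shrink large single-locus effects,
and the package quantifies that bias per estimator and per genome partition
(genome / chromosome / locus) with one-sample Wilcoxon signed-rank tests.

Everything runs on a bundled synthetic generator of two-way admixed
panels: per-individual θ ~ Beta (mean ≈ 0.80, SD ≈ 0.11), Markov ancestry
tracts along the genetic map (redraw rate g per Morgan), and phenotypes
with single-locus or polygenic ancestry effects on a unit total variance.

## Worked example

```python
import numpy as np
from admixvar import (aric_like_config, simulate_panel,
                      simulate_single_locus_phenotype, global_ancestry,
                      scan, effective_tests, bonferroni_alpha,
                      genome_partition_fit)

panel = simulate_panel(aric_like_config(n_individuals=1000, seed=3))
causal = panel.n_loci // 2
y = simulate_single_locus_phenotype(panel.dosages[causal].astype(float), 0.193, 4)

eff = effective_tests(panel)
alpha = bonferroni_alpha(eff.n_eff)
X = np.column_stack([np.ones(1000), global_ancestry(panel)])
res = scan(panel, y, X, alpha=alpha)
print(res.table.iloc[causal][["beta", "p_value", "delta_r2"]])
```

prints (seed 3)

```
beta            0.798
p_value      9.72e-45
delta_r2        0.177
```

i.e. the injected locus — built to explain 19.3% of variance — is recovered
by the fixed-effects scan at ΔR² ≈ 0.18 with overwhelming significance
(`effective tests: 84.8 of 1320 loci -> genome-wide alpha 0.000589`). The
random-effects counterpart:

```python
fit = genome_partition_fit(panel, y, X, None, "centered")
print(fit.proportion, fit.se_proportion)
```

gives the genome-wide REML proportion with its SE. The `examples/`
directory has one narrative script per capability (simulation, similarity
estimators, scanning, variance components, the bias grid, power and
thresholds); each prints its numbers with a line on what they mean. A thin
CLI mirrors the same stages:

```sh
admixvar --seed 1 simulate --n 500 --sigma2 0.1 --out-prefix demo
admixvar similarity --panel demo.panel.tsv --estimator centered --out-prefix demo
admixvar scan --panel demo.panel.tsv --pheno demo.pheno.tsv --phenotype trait --out scan.tsv
admixvar reml --panel demo.panel.tsv --pheno demo.pheno.tsv --phenotype trait --out reml.tsv
admixvar power --n 2600 --r2 0.193 --alpha 2.21e-4
```

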