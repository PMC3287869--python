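# Methods

`raretest` implements a battery of gene-level association tests between a
quantitative trait and rare genetic variation, for unrelated samples and
for pedigrees, plus the simulation machinery needed to study their type-I
error and power. This note documents the statistical models, the defaults
and the numerical choices.

## Setting and notation

A gene *G* contains *J_G* variants; genotypes are minor-allele counts
*x_ij* ∈ {0, 1, 2} for individual *i* at variant *j* (missing allowed).
Input genotypes are first re-oriented so the counted allele has frequency
≤ 0.5 in the full sample (ties at exactly 0.5 keep the input orientation —
a deterministic tie-break). *MAF_j* denotes the minor allele frequency,
computed over non-missing calls; a frequency-threshold *T_maf* selects the
"rare" set {*j* : 0 < *MAF_j* ≤ *T_maf*} (inclusive comparison, applied
uniformly, so a variant at exactly 1% belongs to the 1% set). Monomorphic
variants never enter a collapsing set or the single-marker battery; a gene
whose eligible set is empty yields an `n/a` result rather than an error.

MAFs default to the full analysis sample (all unrelated individuals, or
all pedigree members in family analyses); an option computes them from
founders only.

## Tests for unrelated samples

All tests are built on the Gaussian linear model *Y = Xβ + ε* fitted by
maximum likelihood (not REML, so nested likelihood-ratio statistics have
their textbook chi-square reference). With residual sums of squares RSS₀
(intercept only) and RSS₁ (full model), the LRT statistic is
*N* log(RSS₀/RSS₁).

* **CA / CP** (labels CA1, CA5, CP1, CP5 for *T_maf* = 1%, 5%): the gene is
  collapsed to one scalar per person — CA is the indicator of carrying at
  least one minor allele at any rare variant, CP the proportion of rare
  variants carried — and tested with a 1-df LRT.
* **VT** (variable threshold): for every distinct observed MAF value *t*
  in the gene, the CP variable at threshold *t* is regressed on the trait;
  the statistic is z_max, the largest |z| (slope / standard error) across
  thresholds. Significance is by phenotype permutation, recomputing z_max
  per permutation. |z| is used because quantitative-trait effects can be
  bidirectional; the original formulation does not fix the sidedness.
* **WS** (weighted sum): all gene variants enter (*T_maf* = 0.5) with
  Madsen–Browning weights *w_j* = √(*n_j q_j*(1 − *q_j*)),
  *q_j* = (*m_j* + 1)/(2*n_j* + 2) (add-one smoothing keeps every weight
  positive); the burden is C_i = Σ_j x_ij / w_j and the statistic the |z|
  of the trait on C, assessed by permutation. The weights are estimated
  from the whole sample — the quantitative-trait setting has no
  "unaffected" subgroup to condition on — so they are phenotype-free and
  are computed once rather than per permutation.
* **CMC1 / CMC2 / CMC3** (combined multivariate and collapsing): the
  MAF < 1% variants are CA-collapsed into one column in all flavours.
  CMC1 adds the CA collapse of the 1–5% group (2-df LRT; variants above 5%
  excluded); CMC2 adds each 1–5% variant individually ((k+1)-df); CMC3
  adds every MAF ≥ 1% variant individually with no upper cap. Empty groups
  are dropped with matching df reduction; aliased (linearly dependent)
  columns likewise reduce the df with a warning, since identical rare
  columns are common at small N.
* **SM** (single marker): a 1-df LRT per polymorphic variant with the
  gene-level Bonferroni rule min-p ≤ α/J_G. The reported gene p-value is
  min(1, J_G · min-p), so "gene p ≤ α" reproduces the decision rule while
  keeping one comparable p per gene across methods. All polymorphic
  variants are included regardless of frequency.

Permutation p-values use the add-one estimator
p = (1 + #{stat_b ≥ observed})/(B + 1) with B = 1,000 by default,
shuffling phenotype values against the fixed genotypes; p is therefore
bounded below by 1/(B+1) and never zero.

## Measured-genotype mixed model for families

For pedigree samples the trait is modelled as
*y = Xβ + g + e* with polygenic effect *g* ~ N(0, 2Φσ_g²) — Φ the kinship
matrix from the standard recursive (tabular) algorithm, block-diagonal by
family — and residual *e* ~ N(0, σ_e² I). Collapsed predictors (CA, CP,
WS; bivariate CMC1) are computed from the family genotypes exactly as in
the unrelated analysis and tested by an LRT with 1 or 2 df, re-estimating
both variance components under the null and the full model. The WS
statistic in families uses the tabulated 1-df chi-square p-value rather
than permutation (exchangeability fails under relatedness). The VT test is
structurally excluded: maximizing over thresholds would invalidate the
tabulated reference, and the CLI rejects it in family mode with an
explanatory error.

Fitting is by profile maximum likelihood over the heritability fraction
h = σ_g²/(σ_g² + σ_e²) ∈ [0, 1): the covariance is
σ_t²[(1 − h)I + h·2Φ], and after one eigendecomposition 2Φ = UΛUᵀ the GLS
fixed effects and σ_t² are closed-form given h. A bounded derivative-free
scalar search (tolerance 1e−8 on h) with an explicit check of the h = 0
boundary makes the optimizer deterministic and robust when the polygenic
variance is truly zero (e.g., identity kinship, where the fit collapses to
ordinary least squares). The eigendecomposition is phenotype- and
genotype-free, so it is computed once per pedigree sample and reused
across genes and replicates.

## Stratification adjustment

Population structure is handled by residualizing the phenotype, not by
modifying the tests: principal components are computed from the
common-variant genotype matrix (default MAF ≥ 5%), each column
mean-imputed, centered at 2p and scaled by √(2p(1 − p)) — the Eigenstrat
standardization — and the phenotype is replaced by its OLS residual on the
top k components (default 5). A sign convention (largest-magnitude loading
positive per component) makes the scores bit-reproducible. In a
two-population null with divergent common-variant frequencies and unequal
trait means, the single-marker test is strongly inflated before adjustment
and returns to the nominal level after it; collapsing tests are also
shifted and likewise return toward nominal — reported as a comparative
diagnostic, since the relative robustness of collapsing versus
single-marker tests depends on the gene's frequency spectrum.

## Synthetic data and the replicate engine

The generator mirrors the evaluation design the tests are validated under:
**genotypes are drawn once and held fixed while phenotypes are regenerated
independently per replicate**, and a type-I error or power estimate is the
proportion of replicates with gene p ≤ α (α = 5%, 200 replicates by
default; exact Clopper–Pearson intervals accompany every rate).

Defaults and their rationale:

* Per-variant MAFs: log-uniform on [0.0007, 0.165] — the frequency range
  spanned by rare causal exome variants; calibration runs narrow this to
  [0.001, 0.05] so the gene is genuinely rare-variant dominated.
* Unrelated samples: N = 500, one gene of 20 variants, counts
  Binomial(2, MAF), variants independent by default. A Gaussian-copula
  knob adds exchangeable within-gene haplotype correlation to make
  LD-driven behaviour testable; it is off by default.
* Populations: K subpopulations with Balding–Nichols frequency divergence
  at a configurable F_ST and per-population trait-mean offsets (the
  stratified-null scenario uses F_ST = 0.1 and offsets ±0.3 residual SD,
  a modest continental-scale confounding).
* Families: 150 three-generation pedigrees of eight (grandparental couple,
  two children with married-in spouses, two grandchildren; four founders).
  Founder haplotypes are population draws; offspring are generated by
  Mendelian gene dropping. With fixed genotypes, a family whose founders
  carry no copy of an allele is uninformative for it in every replicate.
* Phenotype: y = population offset + Σ β_c x_c + g + e with β in residual
  standard deviations per minor allele (comparable across MAFs), polygenic
  g (family mode, cov 2Φσ_g², default heritability 0.5 in calibration
  runs) and standard Gaussian e.
* Randomness: one master seed; per-replicate child streams are derived
  from (seed, replicate index) so replicates are order-independent and
  reproducible; permutation streams additionally key on a stable gene tag.

What the generator does **not** emulate: realistic linkage disequilibrium
beyond the exchangeable within-gene knob, site-frequency spectra from
demographic history, genotyping error, missingness patterns, ascertainment
of families, or real exome annotation. Passing calibration here shows the
tests are correct under their stated assumptions, not that real exome data
meet those assumptions.

## Numerical choices and degenerate inputs

* Residual-variance floor 1e−12 × var(y) in all ML log-likelihoods keeps
  LRT statistics finite when a model interpolates exactly.
* Rank-deficient designs are fitted by pseudo-inverse; df is reduced to
  the design rank minus one, with a warning.
* Constant predictors (nobody — or everybody — carries) yield `n/a`.
* Missing genotypes: excluded from MAF denominators; non-carriers in
  CA/CP indicators (conservative); zero contribution in WS by default with
  a per-variant mean-imputation option; mean-imputed in SM/CMC regression
  columns and before PCA standardization.
* Kinship eigenvalues are clipped at zero (tolerance −1e−8) before use.

## Problem sizes used in validation

Calibration suites use 2,000 replicates (CP LRT, SM family-wise error) or
1,000 replicates (WS with B = 1,000 permutations; family MG test on 150
pedigrees), which give an exact-binomial 99% band of roughly ±1.2–1.8
percentage points around the 5% nominal level. Variance-component recovery
averages 200 simulations of 200 sib-pairs at σ_g² = σ_e² = 0.5 and checks
the mean recovered polygenic fraction to ±0.05. The stratification
diagnostic uses 400 replicates on a 16-gene, two-population sample of 500.

## Known limitations

* Binary traits, covariates beyond PC residualization, exact small-sample
  F-tests, dosage data and X-chromosome handling are out of scope.
* The family WS p-value relies on the asymptotic chi-square; at few
  families it can be anticonservative.
* CMC statistics with pseudo-inverse fits are well-defined under aliasing,
  but the reported df assumes the surviving columns are meaningful
  predictors; heavily degenerate genes deserve inspection.
* The kinship algorithm assumes founders are unrelated and non-inbred.
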