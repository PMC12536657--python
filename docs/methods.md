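# Methods

`multipgs` builds and evaluates polygenic scores (PGSs) that combine GWAS
summary statistics from multiple ancestral populations. This note records
the models, the estimators, the numerical choices, and what the built-in
simulator does and does not emulate.

## The problem

A PGS predicts a trait as a weighted sum of allele counts,
`PGS_i = Σ_j x_ij w_j`. When GWASs exist for several populations, one PGS
per population can be derived and the target-population prediction formed
as a linear combination `Σ_k α_k PGS_k` of the population-specific scores
(each standardized to SD 1). The practical obstacle is estimating the
mixing weights α when no individual-level tuning cohort is available. The
toolkit implements both routes:

* **IndivTune** — ordinary least squares of the prepared trait on the
  standardized population PGSs in a tuning sample;
* **SumStatTune** — a LEOPARD-style procedure that needs only the GWAS
  summary statistics and a reference genotype panel.

## Summary-statistic mixing weights (LEOPARD-style)

The reference panel of the target population is split into three disjoint,
population-stratified parts, each providing an independent LD estimate.
Per repeat (default 4, averaged):

1. **Subsample every GWAS** into pseudo training/testing summary
   statistics. With train fraction `f` (default 0.75), the training effects
   are `β_train = β̂ + e`, `e ~ N(0, (1/f − 1) D^{1/2} R D^{1/2})` with
   `D = SE²` and `R` the block LD from reference part 1. This gives
   `β_train` the sampling variance of an `f·N`-sample GWAS, and
   `β_test = (β̂ − f β_train)/(1 − f)` satisfies the exact identity
   `f β_train + (1−f) β_test = β̂`. Standard errors scale by `1/√f` and
   `1/√(1−f)`; sample sizes by `f` and `1−f`.
2. **Train one weight set per population** on its training subset with the
   summary-statistic "auto" shrinkage (below), using LD from part 2.
3. **Estimate the mixing weights** from the target's testing subset:
   `c_k = w_kᵀ β_test` (all in standardized-genotype units),
   `V_kl = w_kᵀ R w_l` accumulated block-wise from part-3 LD,
   `α_raw = V⁻¹ c`, and `α_k = α_raw_k √(V_kk)` so the coefficients apply
   to SD-1-scaled scores. If `cond(V) > 1e8` a small ridge is added and
   the result flagged.

Negative α are allowed (the OLS comparison target permits them). The final
coefficients are the mean of the per-repeat SD-1-scaled α, without
renormalization to sum 1.

## Population-specific weights

* **pT+clump** — exact greedy clumping: visit variants by ascending p
  (ties by chromosome, position); each retained index variant removes
  not-yet-retained variants within the window (default 250 variants) with
  `r² > 0.1`; one weight column per threshold in
  {1e-8, 1e-6, 1e-4, 1e-2, 0.1, 0.5, 1}.
* **shrink_auto** — an infinitesimal ridge requiring no tuning data: per
  LD block, `w = (R + (M/(N h²)) I)⁻¹ β_std`, converted back to per-allele
  units. `h²` can be supplied or estimated (below). This is the weight
  generator used inside the summary-statistic combination machinery; any
  method producing one weight column per population can be injected.

**SNP heritability** is estimated by a minimal LD-score regression:
per-variant χ² against LD scores `ℓ_j = Σ_k r²_jk` (within-block). The
intercept is constrained to 1 by default — the free-intercept slope has
standard deviation ≈ 0.18 at M = 2,000 in 100 LD blocks because χ² values
are block-correlated (about one independent observation per block), while
the constrained estimator achieves ≈ 0.02 with no detectable bias on
simulated data, where confounding is absent by construction. The
free-intercept fit is always reported as a confounding diagnostic and can
be selected with `constrain_intercept=False` (appropriate for real data
where population structure may inflate the intercept). Estimates are
clamped to [0.001, 1] with a flag.

## Harmonization

Summary statistics are aligned to a reference variant table by SNP id.
Strand-ambiguous (A/T, C/G) variants are removed; reversed alleles are
swapped (negating BETA, complementing FREQ); complement-base matches are
strand-flipped. Filters: INFO < 0.9 (skipped when the column is absent),
MAF < 0.01 in GWAS or reference, |FREQ − refFREQ| > 0.2 after alignment,
p outside (0, 1], duplicate ids (all copies removed), and N outside
median ± 3×MAD (plain MAD; applied only when N varies). Rules run
sequentially and each removed record is counted under the first rule it
fails, so report counts are additive. Missing BETA/SE/P are recovered from
the remaining fields (`BETA = ln OR`; `SE = |BETA|/z(P)`; `P` from the z
score); a record with P = 1 and no SE is flagged `se_undefined`.

## Ancestry

Reference principal components come from an SVD of standardized reference
counts (component signs fixed deterministically). Targets are projected
with simple loading projection — no shrinkage correction, a known
divergence from corrected projections, acceptable at the Fst separations
the classifier operates on. A GWAS is projected by treating `2·FREQ` as a
pseudo-individual. Population assignment uses an elastic-net multinomial
logistic model (l1 ratio 0.5, penalty chosen by internal cross-validation)
on 6 PCs, with a hard label only when the predicted probability strictly
exceeds 0.95. Within-population outliers are samples whose distance to
their k-means centroid (k = 5, 10 PCs) exceeds mean + 3 SD of all
within-cluster distances. GWAS ancestry composition is estimated by
non-negative least squares of the GWAS frequency vector on per-population
reference frequencies, renormalized onto the simplex.

## Evaluation

Traits are rank-based inverse-normal transformed (Blom offset 3/8, ties by
average rank), residualized on caller-supplied covariates by OLS, and
scaled to mean 0 / SD 1. Prediction accuracy is the Pearson correlation of
predicted and observed values with `SE = √((1−R²)/(n−2))`. The "top-1"
builder runs seeded 10-fold cross-validation (random equal folds, no
stratification): per fold it picks the best column per source group by
absolute training correlation, fits an OLS combination, and predicts the
held-out fold; the pooled R is computed on the concatenated held-out
predictions, and hyperparameters are re-selected in every fold. Dependent
correlations sharing the observed trait are compared with the
Hotelling-Williams t (df = n−3, two-sided); per-trait correlations are
pooled with the BHHR composite (mean effect; variance
`(1/m²) ΣΣ ρ_ij SE_i SE_j` with ρ the between-trait correlation matrix,
computed from observed phenotypes). Weight calibration is the RMSE between
estimated and observed mixing weights; relative improvement is
`100·(r_a − r_b)/r_b` with a delta-method SE absorbing the cross-model
prediction correlation. No multiple-testing adjustment is applied.

## The simulator

Two or more populations share ancestral allele frequencies drawn per LD
block (uniform in `base_freq_range`, small per-variant jitter — linked
variants share genealogy, and without similar frequencies the attainable
LD is structurally capped below the target). Population frequencies
diverge by a Balding-Nichols model with the configured Fst. Haplotypes are
thresholded latent Gaussians with AR(1) block correlation; the latent
parameter is `sin(π·rho/2)` (inverse tetrachoric at frequency 0.5) so
realized genotype LD approximates `rho` for common variants. Diploid
genotypes are sums of two independent haplotypes (Hardy-Weinberg).

Causal variants form one shared set across populations (fraction `1−pi0`);
effects are multivariate normal with cross-population correlation `rg` and
are rescaled so the realized genetic variance equals `h²` exactly in each
phenotype sample. GWAS output is per-variant marginal OLS on allele
counts, so `E[χ²] ≈ 1 + N h² ℓ/M` holds by construction.

What it does **not** emulate: recombination-map LD (blocks are
homogeneous AR(1)), population-private causal variants, admixed
individuals and local ancestry, imputation error (INFO is fixed at 1;
INFO filtering is tested with hand-built fixtures), case-control traits,
and confounding (no structure in the phenotype noise). Passing tests
demonstrate internal consistency of the estimators under a correctly
specified model, not robustness to real-data misspecification such as LD
reference mismatch.

## Study conditions used by the built-in experiments

The experiment drivers (`multipgs.experiments`) run two populations,
M = 2,000 variants in 100 blocks of 20 (AR(1) rho 0.5, Fst 0.1), h² = 0.3,
pi0 = 0.5, rg = 0.7, GWAS N = (2,000, 20,000) with the small GWAS matching
the target population (a reduced-scale version of the motivating
African/European sample-size imbalance), target n = 2,000, and a reference
panel of 900/population split into stratified thirds. At this scale the
full 10-replicate study runs in a few minutes on one CPU. A consequence of
these conditions worth knowing: the two population PGSs end up with
near-equal predictive value, so the true mixing weights are nearly tied;
comparisons that hinge on which component gets the larger weight, or on
whether individual-level tuning beats summary-statistic tuning, are
statistical ties here (the summary-statistic weights are within RMSE
≈ 0.04 of the individual-level ones).

## Numerical conventions

* LD block matrices are ridge-regularized, `R ← (1−ε)R + εI`, ε = 0.01
  (small reference panels give singular blocks); zero-variance variants
  get identity rows and a flag.
* Clumping ties on p are broken by (CHR, BP); all algorithms are
  deterministic given their seed, and every CLI stage rerun with the same
  inputs is byte-identical.
* Mean imputation (2×frequency) for missing genotypes, PLINK `--score`
  semantics for weight application, weights negated when the effect allele
  matches the panel's A2.
* Reference splits, folds, k-means, the elastic-net solver and all
  simulation draws consume seeds derived from user-supplied integers via
  `numpy.random.SeedSequence`.

## Known limitations

* The summary-statistic combination is a "LEOPARD-style" construction
  (conditional-normal subsampling + summary-statistic least squares); it
  is not a reimplementation of any published tool's internals, and the
  "auto" shrinkage stands in for heavier single-source methods on the
  assumption — shared by the framework it models — that mixing weights
  depend only weakly on the single-source method.
* PC projection omits shrinkage correction; projected targets sit
  slightly closer to the origin than reference samples at equal ancestry.
* The harmonizer adjudicates duplicates by removal, never by choosing a
  copy; real pipelines with multi-allelic sites may prefer smarter keys
  (CHR:BP:alleles fallback is available).
* Liability-scale conversion, effective-N computation for case-control
  GWAS, and binary-trait metrics are out of scope.
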