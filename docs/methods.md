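# Methods

## The problem

Sparse polygenic scores (PGS) trained directly on genotype matrices —
rather than on GWAS summary statistics — are among the best-performing
predictors for many human traits, but a single L1-penalized ("LASSO")
regression over ~50,000 SNVs and hundreds of thousands of individuals
needs hundreds of gigabytes of memory. `blocklasso` exploits the
biological fact that linkage disequilibrium (LD) is negligible between
chromosomes: the SNV correlation matrix is approximately block-diagonal,
so the penalized regression can be solved independently per chromosome
("block") and the per-block scores recombined afterwards.

## The model

The training objective, per block or globally, is

    O(λ) = (1/2N) ‖y* − X β‖₂² + λ ‖β‖₁

with y* the covariate-residualized phenotype, X the (column-standardized)
dosage matrix, and λ the penalty. The pipeline has six stages:

1. **Splits.** A fixed test set (default 20%) is withheld; the remainder
   is split into K=5 cross-validation folds, each providing a training
   set and a model-selection (validation) set.
2. **Residual phenotype.** Continuous traits are z-scored within each
   sex (training statistics), then age and genetic principal components
   are removed by OLS. Case-control labels stay on the 0/1 scale and are
   residualized by linear (not logistic) least squares, so that a single
   Gaussian-loss objective serves both trait types. The fitted transform
   is applied unchanged to held-out samples.
3. **Feature ranking.** A single-marker scan (simple regression of y* on
   each dosage, t-test p-values with n−2 df) ranks SNVs within each
   block (or genome-wide for the global baseline); SNVs with training
   minor-allele frequency ≤ 0.001 are excluded; the top k per block
   enter the LASSO. Nothing but the rank order is retained.
4. **Per-block LASSO.** Coordinate descent (scikit-learn) with warm
   starts down a log-spaced path of 100 penalties from λ_max (the
   smallest penalty with an all-zero solution, max|x_jᵀy|/N) to
   10⁻³·λ_max. The penalty is chosen by maximal validation-set metric;
   ties go to the larger penalty.
5. **Block re-weighting.** Per-block linear scores s_b = Σ_j β_bj X_bij
   are regressed (OLS with intercept) against the **raw** phenotype on
   the validation fold, giving block weights α_b. Null blocks are
   excluded from the regression and get α=0.
6. **Evaluation.** Each fold's stitched model is applied to the common
   withheld test set; the reported metric is the fold mean, with
   σ_cv-SD the fold standard deviation.

### Uncertainties

Reported metric SDs combine two terms in quadrature:
σ_AUC ≈ √((1/(3√N_cases))² + σ_cv²) and
σ_corr = √((1−ρ²)/(N−2) + σ_cv²). The 1/3 constant in the AUC rule is an
empirical convention taken as given. Agreement between block and global
scores is *full* when the ±1σ_total intervals overlap, *approximate*
when the relative loss — (corr_g−corr_b)/corr_g, or
(AUC_g−AUC_b)/(AUC_g−0.5) for AUC — is at most 20% (boundary included,
with a 1e-9 float epsilon), and *none* otherwise. The loss fraction is
deliberately asymmetric in its arguments.

### Variance profile

With H_ij = α_b β_bj X_bij, the feature covariance K = Cov(H) is
block-diagonal by construction (cross-block entries are zero by the
independence assumption, never computed). Row sums of K attribute
Var(PGS) to single SNVs; the attribution is exact (conserved to
rounding) and entries can be negative for anti-correlated features. For
display the profile is filtered (|contribution| < 0.01% of the total
dropped, *before* binning — the procedural order is a package choice)
and binned greedily left-to-right in 1 Mbp windows: a new bin opens when
a variant lies more than the bin width beyond the current bin's first
member. Bin position is the |contribution|-weighted mean position; bin
SDs combine in quadrature. Covariances use the n−1 denominator.

## The simulator

The generator emulates chromosome-partitioned biobank genotypes, not any
particular coalescent process:

- per-SNV allele frequency ~ U(maf_range), default (0.001, 0.5) — the
  lower bound mirrors the selection cut;
- two latent Gaussian AR(1) haplotype processes per sample with
  inter-SNV correlation exp(−ld_decay·Δindex), thresholded at
  Φ⁻¹(MAF) and summed, giving {0,1,2} dosages with Binomial(2, MAF)
  margins and controllable within-block LD. `ld_decay = 0` is the
  declared no-LD case (independent SNVs), not the degenerate φ=1 limit
  of the formula. Default ld_decay = 0.2: adjacent latent correlation
  ≈ 0.82 decaying to ≈ 0.14 at 10 SNVs, a plausible LD scale when 250
  SNVs span 100 Mbp;
- positions evenly spaced over block_span_bp (default 100 Mbp) from a
  random per-block start; blocks are mutually independent.

Phenotypes are additive: causal SNVs placed uniformly across all blocks,
effects β ~ U[0,1), and noise a·U[0, σ_g) with σ_g the realized SD of
the genetic score. The one-sided noise is kept literally as stated — its
nonzero mean shifts location only. Since Var(U[0, a·σ]) = a²σ²/12,

    h² = 12 / (12 + a²)   (a=2 → 0.75, a=5 → 12/37 ≈ 0.324)

and corr(genetic, phenotype) → √h², closed forms used as oracles
throughout the tests.

**What the simulator does not emulate:** population structure and
admixture, recombination-map LD (AR(1) by index is stationary),
realistic site-frequency spectra, genotyping error/missingness, and
covariate effects (simulated traits need no residualization). A green
simulation test therefore establishes the pipeline's statistical
machinery, not robustness to those real-data features.

The desk-scale validation scenario (defaults of `SimConfig`) is 22
blocks × 250 SNVs × 2,500 samples with 50 causal SNVs, studied at error
scales 2 and 5 and at 250 causal SNVs.

## Numerical choices

- Coordinate-descent tolerance 1e-4 (max coefficient change), at most
  10,000 sweeps; path of 100 penalties, ratio 1e-3 — standard practice,
  chosen for cross-platform reproducibility. No early stopping along the
  path by default (weak signals make a stopping point unreliable).
- Features are standardized with training-fold mean/SD; zero-SD
  features are dropped with a warning. Weights are stored on the
  standardized scale together with the constants, so original-scale
  weights (β_std/sd) reproduce standardized predictions exactly.
- Validation-metric ties select the larger penalty (sparser model);
  p-value ties in ranking break by ascending base-pair position. Both
  rules are deterministic across platforms.
- A block whose fit fails yields a flagged null model and the run
  continues; block results are independent of execution order.
- The α regression includes an intercept (the raw phenotype is not
  centered) and the final score adds it; this is irrelevant to
  correlation/AUC but makes scores location-consistent.
- Case-control residuals pass to the LASSO unclipped and uncentered.
- The same validation fold serves both penalty selection and α fitting;
  this mirrors the single "model-selection set" design and carries a
  known risk of mild optimism in the α's.
- Frequency cut: counted-allele frequencies are not minor-allele folded;
  the cut applies to min(f, 1−f).

## Known limitations

- The global baseline at 5,500 pooled features is ~10× slower than the
  22 block fits combined — the expected block-diagonal speedup, but it
  makes the global path the runtime bottleneck of the validation study.
- Linear (not logistic) scans and LASSO for case-control traits: AUC
  rankings are insensitive to this, calibrated probabilities are out of
  scope.
- The PLINK 1 reader loads the whole .bed into memory; file-backed
  matrices are out of scope.
- Agreement classification depends on the ±1σ convention; with very
  large samples "full" agreement becomes nearly unattainable by design.
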