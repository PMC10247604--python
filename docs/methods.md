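# Methods

This note records the statistical models implemented in `hapsparse`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Genotype model and quality control

Genotypes are biallelic SNP dosages in {0, 1, 2} (copies of the ALT
allele) on inbred or phased-homozygous lines.  Processing order is fixed:
heterozygous calls (dosage 1) are set to missing *before* any frequency is
computed; SNPs are then removed when MAF < 0.05 or missing rate > 0.1,
both strict inequalities, so boundary values are retained and a SNP
failing both rules is counted once under MAF.  MAF is defined over
non-missing calls; an all-missing column is removed under the missing-rate
rule without ever dividing by zero.  Missing dosages are imputed with the
SNP's mean over fingerprinted lines only at the point where a variant set
is assembled, which conserves allele frequencies exactly.

## Haplotype blocks

Pairwise LD uses two-locus haplotype counts; each inbred line contributes
its single homozygous haplotype twice, matching diploid counting.  The
90% confidence interval of |D′| is obtained by evaluating the multinomial
likelihood of the observed counts on a uniform 1001-point grid of |D′| in
[0, 1], with allele frequencies held at their sample estimates, then
normalizing and reading the 5th/95th cumulative percentiles.  Pairs are
classified strong LD (CI low ≥ 0.70 and CI high ≥ 0.98), strong
recombination (CI high < 0.90), or noninformative; pairs more than 200 kb
apart are never evaluated, and pairs with fewer than 10 complete
haplotypes (5 lines) are noninformative.

A candidate span is any contiguous SNP run whose outermost pair is strong
and in which at least 95% of informative pairs are strong; at least one
informative pair is required, so no block rests on zero evidence.
Candidates are accepted greedily by bp length (descending), ties broken by
leftmost start — a deterministic tie-break where tool internals are
usually silent.  The uniform 95% rule applies to every span size; no
special small-span frequency rules are used.  Segmentation splits each
block left-to-right into fragments of exactly 2 or 3 SNPs; a trailing
remainder shorter than the fragment length becomes its own fragment, and a
1-SNP fragment is routed back to the plain-SNP set rather than being
treated as a haplotype (the remainder rule is a declared choice, not an
inherited one).

## Haplotype coding and relationship matrices

Within each used block, every distinct observed haplotype string is an
allele column; a line carries 2 copies of its haplotype, or 0 in every
column of a block where a missing member call makes its haplotype
unresolvable (such lines are also excluded from that block's frequency
denominator — conservative, no haplotype imputation).  Rare alleles are
filtered at the same strict 0.05 threshold as SNP MAF (the threshold is a
package choice, mirroring genotype QC), after segmentation for fragment
codings; a block losing all informative alleles is dropped and its SNPs
return to the plain-SNP set.  Fragment allele ids are namespaced by block
and fragment index so 2- and 3-SNP codings coexist.

All relationship matrices use

    K_ii' = (1/p) * sum_m (x_im - 2 d_m)(x_i'm - 2 d_m) / (2 d_m (1 - d_m)),

where d_m is the column frequency (column mean / 2, identically for SNPs
and haplotype alleles).  Columns with d_m in {0, 1} are rejected rather
than silently skipped.  K is not jittered; samplers floor eigenvalues at
1e-8 of the largest when factorizing.  For fully inbred dosages the
diagonal averages ≈ 2 (1 + inbreeding excess), which is expected and left
unscaled.

## Two-stage phenotypic analysis

Stage 1, per environment: y = 1μ + X_w w + Z_l l + ε with design effects
(replicate, row, column — whichever exist in the data, config-driven)
i.i.d. random.  Lines are fit once fixed (cell-means coding; the GLS
estimates are the environment-specific BLUEs; a line absent from an
environment simply has no BLUE) and once random, giving the Cullis
repeatability 1 − c̄/(2σ²_g) with c̄ the exact mean variance of a BLUP
difference over all line pairs (populations here are ≤ ~1100 lines, so the
exact pairwise mean is affordable).  Stage 2 combines BLUEs with random
environment and line effects and reports the Cullis heritability the same
way; inputs that are already spatially adjusted can enter stage 2
directly.  Stage 2 is unweighted — no stage-1 precision weights — matching
the model's form.

REML is maximized directly with L-BFGS-B on log variance components,
evaluating the restricted likelihood through the Henderson MME coefficient
matrix (one Cholesky of a (p+q)×(p+q) system per evaluation, with
cross-products precomputed).  At these problem sizes this is faster and
more robust than EM iteration; convergence tolerance is 1e-8 on the
objective with at most 500 iterations.  Variances are bounded below at
1e-8 × var(y); an estimate at the bound is reported (effectively zero)
with a logged warning, and derived ratios are clamped to [0, 1].

## Multi-environment genomic prediction

All three models regress environment-specific BLUEs ŷ on K via Gibbs
sampling; masked or missing cells contribute to no likelihood term.

* **VG**: ŷ = 1μ + Z_v v + Z_g g + e, v ~ N(0, Iσ²_v), g ~ N(0, Kσ²_g),
  e ~ N(0, Iσ²_e).
* **VGR** adds r ~ N(0, (Z_v Z_v′ ∘ Z_g K Z_g′) σ²_r).  The Hadamard
  kernel is block diagonal by environment, so r is sampled per environment
  as a Gaussian process with covariance Kσ²_r in the eigenbasis of K.
* **FA(1)**: per-environment genetic effects u ~ N(0, Ψ_u ⊗ K) with
  Ψ_u = ΛΛ′ + Π (t = 1 factor), residuals ε ~ N(0, Ψ_ε ⊗ I) with diagonal
  Ψ_ε.  The sampler uses the decomposition g_j = λ_j f + d_j with
  f ~ N(0, K) and d_j ~ N(0, K π_j), which reproduces Ψ_u ⊗ K exactly and
  gives conjugate updates throughout.  Identifiability: the sign of
  (Λ, f) is flipped whenever the first loading goes negative, per draw.

Numerics.  Samplers run on the phenotyped lines; effects of unphenotyped
lines are recovered by the conditional-mean projection
K[test, train] K[train, train]⁻¹ applied to posterior means — identical to
carrying them in the chain, since predictions are posterior means of
linear functionals.  When every training line is observed in an
environment (complete data, or missing rate 0) the conditional precision
of each Gaussian-process update is diagonal in the precomputed eigenbasis
of K, making an update O(n²); under masking a dense Cholesky per update is
taken instead.  Eigenvalues of K are floored at 1e-8 of the largest.

Priors.  Every variance has a scaled inverse chi-square prior with 5
degrees of freedom, scale set so the prior mode equals an equal split of
the phenotypic variance across model terms (3 terms for VG and FA, 4 for
VGR); loadings have a Gaussian prior with mean 0 and variance equal to the
phenotypic variance.  These hyperparameters are declared configuration —
defaults of the reference Bayesian tooling are not published, and no claim
of matching them is made.  Chain settings default to 10,000 iterations,
4,000 burn-in, thin 1; only post-burn-in draws are stored.  A Geweke
z-score on the variance chains is exposed as a convergence check.

## Sparse-phenotyping CV1

Lines are partitioned into 5 random folds (sizes within one); four train,
one tests; 10 CV repeats and, per missing rate, 10 masking repeats give
5 × 10 × 10 = 500 calibrations per rate.  Masking shuffles training lines
and masks one randomly chosen environment-specific BLUE per line, taking
further per-line passes if one per line is not enough, until exactly
⌈rate × n_cells⌉ cells are masked.  The whole pattern is rejected and
redrawn from a fresh sub-seed until every environment's missing fraction
lies strictly in (rate/2, 1); rejection (rather than in-place repair)
keeps the marginal distribution of accepted patterns simple and auditable.
After 1000 rejections the balance constraint is reported as infeasible.
At rate 0 masking repeats collapse to one distinct training set and the
engine deduplicates.

Accuracy is computed per environment as the Pearson correlation between
the concatenated test-set predictions of one CV repeat and the observed
BLUEs (per-environment is primary; environment-averaged summaries are also
emitted).  Zero-variance vectors yield an undefined (missing) accuracy,
never 0.  Model comparisons transform accuracies with Fisher's
z = 0.5 ln((1+r)/(1−r)) and use a paired two-sided Student t-test across
(CV repeat, masking repeat, environment, rate) cells at α = 0.05.

## Synthetic data generator

Founder haplotypes are tiled by ancestry blocks (lengths uniform in
40–160 kb by default); within a block each of 8 founders carries one of
2–4 distinct haplotype strings, so intra-block LD is near-complete while
recombination hotspots (5 Morgans) at block boundaries decouple adjacent
blocks.  RILs are produced by a multi-way crossing funnel (8 → 4 → 2 → 1)
of gametes recombined under a Haldane map (Poisson crossover counts on a
uniform 4 cM/Mb background), then made instantly homozygous,
doubled-haploid style — the pedigree of a real RIL population (selfing
generations, residual heterozygosity) is not reproduced.

Per-environment genetic values follow u_ij = λ_j f_i + √π_j s_ij.  The
factor score f and specifics s_j are linear in the genome: a mix of
additive SNP effects and complete-block haplotype-allele effects in
proportion (1 − local_epistasis_frac) : local_epistasis_frac, Gaussian
coefficients.  Scores are Gram-Schmidt-orthogonalized in sample — under
block LD the genome's effective dimension is small enough that raw random
scores correlate noticeably, which would make the realized
between-environment covariance drift from ΛΛ′ + Π.  Plot records add an
environment mean, random replicate/row/column effects (variance 0.05 each
by default) and residual noise calibrated so the line-mean heritability
per environment hits the target (default 0.8, 3 replicates, 4
environments, 300 lines — a mid-scale MET).  Truth tables (genetic values,
factor scores, realized correlations, generating blocks) are returned for
recovery tests.

What passing tests on this generator do *not* show: robustness to
genotyping error beyond random missingness, population structure or
family stratification, selection, non-Gaussian effect distributions,
spatial field trends beyond iid row/column effects, or unphased
heterozygous data.

## Problem sizes used in the test and acceptance studies

Simulation studies run at n = 150–300 lines, 3–4 environments, 800–1,500
sampler iterations, 1–2 CV repeats — sizes chosen as the package's own
desk-scale study conditions; the properties asserted (oracle equivalence,
recovery RMSE, masking contracts, accuracy orderings) are size-stable.
The public-population QC count check requires the external repository
download of the 344-line panel and only runs when that file has been
placed under `data/dryad_pop1/`.

## Known limitations

* FA with t > 1 is not a validated path; the single-factor model is.
* No EM-based haplotype frequency estimation: inputs must be inbred or
  phased (unresolvable haplotypes get zero dosage).
* Stage-1 spatial adjustment uses iid row/column effects, not AR1×AR1
  correlation structures.
* No training-set optimization (CDmean-style) or CV2/leave-one-environment
  schemes; masking is purely random within the stated balance constraint.
* Alternative GRM scalings (trace normalization, pedigree matrices) are
  out of scope.
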