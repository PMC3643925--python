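# Methods

This note records the statistical model behind `snpset`, the choices made
where the methodology is genuinely open, and what the simulation studies do
and do not establish.

## Genotype simulator

**Latent-Gaussian haplotypes.** A haplotype over p SNPs is generated as
`a_j = 1{Z_j < Φ⁻¹(q_j)}` with `Z ~ N(0, R)`, `q_j` the minor-allele
frequency of SNP j and `R` a latent correlation matrix. For every pair
(i, j) with target allele-scale Pearson correlation `r_ij`, the latent entry
`ρ_ij` solves

    Φ₂(Φ⁻¹(q_i), Φ⁻¹(q_j); ρ) = r_ij·√(q_i(1−q_i)q_j(1−q_j)) + q_i q_j

by Brent root finding on the bivariate-normal orthant probability (the
orthant probability is monotone in ρ). Because the indicator correlation is
matched *exactly*, the realised pairwise R² of simulated haplotypes equals
its target up to Monte-Carlo noise — naive thresholding constructions
instead realise less LD than the matrix they are fed. Targets are specified
as R²; the allele correlation is taken as `+√R²` (positive LD). A common
*negative* correlation of 10–100 variables is not positive definite, so the
positive root is the only sign convention under which the equicorrelated
designs exist; `negative_ld=True` is available for small sets.

Requested correlations are checked against the Fréchet bounds for the two
Bernoulli margins (e.g. R² = 0.4 between MAF 0.10 and MAF 0.25 indicators is
impossible; the error message reports the attainable range). Entrywise
solutions need not be jointly positive definite for arbitrary target
matrices, so the assembled matrix is repaired by clipping eigenvalues at
1e-8, reconstructing, and rescaling to unit diagonal; the Frobenius repair
distance is stored on the model (0 for all built-in scenarios).

**Fitting to a panel.** `fit_model_from_haplotypes` estimates `q_j` as
column means (columns with frequency > 0.5 are flipped and recorded) and
pairwise allele correlations from joint frequencies, then inverts each to a
latent correlation as above. Duplicated columns (allele correlation 1) are
clipped to 1−1e-9 with a warning and then perturbed by the PD repair.

**Diploids and disease.** Genotypes are sums of two independent haplotypes,
hence in Hardy-Weinberg proportions in expectation. Disease follows

    logit P(Y=1 | g) = β₀ + Σ_c ln(GRR_c)·g_c ,

an additive-in-allele-count multiplicative-odds model in which GRR is the
per-allele odds ratio — the standard GWAS simulation convention. β₀ is
calibrated by 1-D root finding so the population prevalence equals a target
(default 0.10); the population mean of P(Y=1) is evaluated *exactly* from
the joint genotype distribution at the causal loci (orthant probabilities +
inclusion-exclusion, convolved for the two haplotypes) for up to 6 causal
SNPs, with a fixed-seed Monte-Carlo quadrature beyond. Case-control samples
are accumulated by rejection sampling (capped at 10⁷ draws). Under a null
scenario the phenotype is independent of genotype, so exactly
n_cases + n_controls genotypes are drawn and a shuffled label vector is
attached — distributionally identical to rejection sampling and an order of
magnitude cheaper at prevalence 0.10.

**Built-in scenarios.** A1–A9 cross three MAF levels (0.05/0.1/0.2) with
three disease models (null; one causal SNP at per-allele GRR 1.3; two causal
SNPs at GRR 1.2 each), each at pairwise R² ∈ {0.2, 0.5, 0.8}, with 10 or
100 SNPs and 1,000 cases / 1,000 controls. Causal SNPs sit at index 0 (and
1): the designs are exchangeable (common MAF, equicorrelated LD), so the
placement is distributionally irrelevant; the spec of a scenario accepts
arbitrary indices for non-exchangeable custom designs.

## The four set tests

**PCA.** Covariance (not correlation) of the additive genotype codes is
eigendecomposed; k is the smallest component count reaching 80% cumulative
eigenvalue fraction; the phenotype is tested on the k scores by a logistic
likelihood-ratio chi-square with k df against the intercept-only model.
Eigenvector signs are fixed (largest-magnitude loading positive) and
rank-deficient score designs drop dependent columns with a warning. The LRT
was chosen over the Wald form because its df accounting is explicit; on
these designs the two are numerically indistinguishable.

**Supervised PCA.** Screening statistic: `|U_j|/√V_j` with
`U_j = Σ_i (y_i − ȳ)g_ij`, `V_j = ȳ(1−ȳ)Σ_i (g_ij − ḡ_j)²` — the two-group
score statistic of the allele count. Candidate thresholds are the
{0, 0.25, 0.5, 0.75, 0.9} quantiles of the screening statistics; for each
threshold the selected SNPs' first principal component is the predictor of a
single-predictor logistic LRT, and the reported statistic is the maximum
over thresholds. Inference is by full-procedure phenotype permutation:
every permutation re-runs screening, selection, PC1 extraction and the
maximisation, so the selection step is inside the null distribution —
selection-aware asymptotics are thereby unnecessary, at the price of
computation. Permutations stop early by the Besag–Clifford sequential rule
(stop at h = 10 exceedances, p̂ = h/L; else p̂ = (c+1)/(B+1) at the budget
B = 1000), which is unbiased-valid and makes null replicates cheap.
Permutation batches run in float32 (observed statistics in float64); the
statistic difference is ~1e-6, far below permutation resolution. If every
threshold somehow screens out all SNPs the full set is used and flagged.
A fixed absolute-threshold mode (`fixed_screening_threshold`) is provided
for sensitivity analyses against the adaptive grid.

**Kernel PCA.** `K_ij = exp(−‖g_i−g_j‖²/2σ²)`, double-centred; components
to 80% of the trace, capped at min(n−2, 50) to bound the df of the
subsequent LRT. The automatic bandwidth sets σ² to twice the *mean*
pairwise squared distance. The more common median heuristic degenerates on
genotype data: with rare alleles and strong LD, more than half of all
individual pairs have *identical* genotype vectors, the median distance is
exactly zero, and any near-median bandwidth produces a nearly diagonal
kernel whose flat spectrum forces dozens of components and a badly
inflated chi-square test (measured type-I error ≈ 0.11 at MAF 0.05). The
mean-distance bandwidth keeps the kernel smooth: roughly 10 components at
MAF 0.05/R² 0.2 and 2 at MAF 0.2/R² 0.8, with measured type-I error
0.042–0.058 across those extremes — consistent with the few-component,
calibrated behaviour this method family reports in practice. The
bandwidth is deterministic and exactly row-permutation invariant (all
pairwise distances are computed for the kernel anyway, so no subsampling
is involved). With a `linear` kernel the procedure is algebraically
identical to the PCA test (kernel-PCA duality), which the test suite
asserts to 1e-8.

**SIR.** Predictors are standardised with the sample mean and inverse
square root of the sample covariance, computed by eigendecomposition with a
relative pseudo-inverse tolerance of 1e-8 (near-null variance directions
are dropped and flagged, but the test df is *not* reduced). With a binary
phenotype there are H = 2 slices and the between-slice covariance
`V = Σ_h p̂_h m̄_h m̄_hᵀ` has one nonzero eigenvalue
`λ₁ = p̂₀p̂₁‖z̄₁ − z̄₀‖²`. The marginal dimension test uses
`T = n·Σλ̂ ~ χ²_{p(H−1)}`, the standard test of "dimension 0" in SIR
software; for H = 2, T is the Hotelling two-group form computed with the
*total* (not pooled within-group) covariance, which shrinks T by the factor
1/(1 + T²/n) relative to the classical T² and makes the test conservative
when p is an appreciable fraction of n. This conservatism is real and
intended: at p = 100, MAF 0.05, R² 0.8 the measured type-I error is ~0.002.

## Study sizes, numerics, reproducibility

All replicate studies draw replicate i from `default_rng(base_seed + i)`;
datasets are shared across methods within a replicate; results are
byte-identical for any worker count because no randomness crosses replicate
boundaries. The test suite and `scripts/acceptance.py` use single-CPU study
sizes: 4,000 replicates for the 10-SNP null cells (twice the classical
2,000-replicate design, halving the Monte-Carlo SE to ≈ 0.0034), 2,000 for
the 100-SNP cells, 1,500–4,000 for SPCA null cells, 500 for KPCA null
cells, and 300 power replicates per scenario with the B = 1000 adaptive
permutation budget (power-cell SE ≈ 0.026).

Numerical conventions: orthant probabilities at abseps 1e-14; copula root
finding to xtol 1e-12 with a 1e-6 post-check on the achieved indicator
correlation; eigenvalue clipping floors at 1e-8; logistic Newton to step
tolerance 1e-10 with step damping, and perfect separation detected
(|η| > 30) and resolved by a small-ridge refit flagged in diagnostics; ties
in screening ranks broken by SNP index everywhere.

## What the synthetic studies show — and what they do not

The generator reproduces the *designed* features of case-control genotype
data: exact target MAF and pairwise R², Hardy-Weinberg genotypes,
multiplicative per-allele disease odds, exact case/control counts. It does
not model haplotype-block LD decay, recombination hot spots, rare-variant
site-frequency spectra, missing genotypes, genotyping error, covariates or
population stratification. Calibration and power results on these designs
therefore characterise the tests under clean, exchangeable LD — the regime
the virtual scenarios define — and transfer to real panels only insofar as
a fitted panel model (`fit_model_from_haplotypes`) captures the real LD.

Two behaviours deserve explicit caveats. First, the SPCA screening rule
(quantile grid + max) is one concrete implementation of
supervised-component screening; other rules (cross-validated single
threshold) shift power by a few points, and the permutation null makes any
such rule valid. Measured SPCA power on the single-causal scenarios runs
roughly 3–7 percentage points above the published reference values of this
design family while preserving ordering and monotonicity. Second, the
100-SNP strong-LD PCA cell is sensitive to the simulator's realised LD:
with exact-target LD the leading eigenvalue fraction is ≈ 0.9, one
component is selected, and the test is essentially calibrated (~0.048);
generators that realise less LD than targeted select many near-degenerate
sparse components and become conservative. We report what the exact-LD
construction yields rather than tuning the generator to any particular
published cell.
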