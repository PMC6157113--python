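# Methods

This note documents the statistical procedures, the generative model
behind the synthetic data, the numerical choices, and the limits of what
the validation studies demonstrate.

## Kernel score test

**Null model.** The covariate-only fit regresses post-treatment lnTG on
an intercept, pre-treatment lnTG, and age by ordinary least squares. The
error variance defaults to the maximum-likelihood convention
σ̂² = RSS/n; a REML flag (`reml=True`, divisor n − p) is available.
Residual orthogonality to the design (|Xᵀr|∞ ≤ 1e-8·scale) and σ̂² > 0
are enforced invariants; an exact linear fit or a rank-deficient design
is an error that names the collinear column.

**Kernel.** K = Z′Z′ᵀ with Z′ the region's marker matrix after column
mean-centering (default on). With an intercept in the null model,
centering cannot change the test — the covariate projection annihilates
column means — so the option only affects the interpretation of K
itself; the equality of centered and uncentered p-values is a regression
test. No marker weighting is applied.

**Statistic and null distribution.** Q = rᵀKr/(2σ̂²) is computed in the
factorized form ‖Z′ᵀr‖²/(2σ̂²) (algebraically identical, exactly
non-negative). Under the null, r = Pε with P the projection complement
of X, so the plug-in null distribution is Σᵢ λᵢ χ²₁ with weights
λᵢ = eig(PKP)/2 — the σ̂² in Q's denominator cancels against the
residual variance it estimates. The spectrum is taken from the m × m
Gram matrix (PZ′)ᵀ(PZ′) when m < n and from the n × n projected kernel
otherwise (similar matrices; the routes agree to 1e-8 and are tested
against each other). Weights below 1e-10 of the largest are truncated;
if the whole spectrum is numerical noise relative to tr(K)/2 the region
is reported degenerate with p = 1 and a warning (this happens when the
markers lie in the covariate column space).

**P-values.** The default p-value is the *exact* Gaussian tail that also
accounts for the sampling variability of σ̂²:

    P(Q > q) = P(εᵀ P (K − c I) P ε > 0),   c = 2q/d,

with d the variance divisor (n for ML, n − p for REML). The weights are
ηᵢ − c for the non-zero eigenvalues ηᵢ of PKP plus −c with multiplicity
n − p − k, and the tail at threshold zero is evaluated by
characteristic-function inversion (method flag `davies`). At n = 111
this correction matters: the plug-in mixture alone is measurably
miscalibrated (its null p-values fail a KS uniformity test at the 1%
level over a few thousand replicates), while the exact form is
calibrated and agrees with the residual-permutation oracle to within
Monte-Carlo error. For m = 1 the exact form reproduces the single-marker
regression t-test p-value to near machine precision, which is the
formal version of "a ±0 kbp kernel window behaves like simple
regression". As n grows the exact and plug-in tails converge.

**Numerical inversion.** The Imhof-form integral

    P(S > q) = 1/2 + (1/π) ∫₀^∞ sin θ(u) / (u ρ(u)) du,
    θ(u) = ½Σ arctan(λᵢu) − ½qu,   ρ(u) = Π (1 + λᵢ²u²)^¼,

is split at u = 1 after rescaling the weights by λmax: adaptive
quadrature on the head plus QUADPACK's Fourier integrator (QAWF) on the
oscillatory algebraic tail, via sin(φ − qu/2) = sin φ cos(qu/2) −
cos φ sin(qu/2). Target absolute accuracy is 1e-6 (achieved ~1e-9 in
practice, ~6 ms per call). For the exact ratio form the total weight
count is n − p and the integrand decays like u^(−1−(n−p)/2), so plain
adaptive quadrature to infinity suffices. If an inversion reports
failure or a p-value outside [−1e-6, 1 + 1e-6], the code falls back —
exact → plug-in mixture → Satterthwaite scaled chi-square matching mean
and variance — and flags the method used; fallbacks are never silent.

**Permutation oracle.** Residuals are permuted with a seeded generator,
re-projected onto the covariate complement, the error variance is
re-estimated, and Q recomputed against the fixed kernel (Freedman–Lane
style), so each permuted Q is the same functional of permuted data that
the observed Q is of the data. The add-one estimator
(1 + #{Q* ≥ Q})/(1 + B) avoids p = 0. Permuting without re-projection
biases the permutation null noticeably at n ≈ 100 (the permuted
residuals leave the projection space), which is why the re-projection is
part of the contract.

**Multiple testing.** Raw p-values are reported; a Benjamini–Hochberg
column is available behind `--adjust-bh` and off by default.

## Region construction

Positions are 1-based inclusive; windows keep markers with
|pos − anchor| ≤ w·1000 on the anchor's chromosome, both boundaries
inclusive, so a 0-kbp window is exactly the anchor (plus any marker at
the identical position). Members are sorted by position; membership is
independent of the universe's input order, and w₁ ≤ w₂ implies a member
subset. Explicit-list regions keep the given order, deduplicate with a
warning, and have no anchor. "Nearest CpG to a SNP" means minimal
|Δposition| on the same chromosome with ties broken toward the lower
position, then the lexicographically smaller id — deterministic by
construction.

## Interaction regression

OLS of the response on intercept + covariates + g + m + g·m with
two-sided t-tests (SE divisor n − p; this is a different fitted object
from the KST null model, which uses the ML divisor). The product is
formed from the raw, uncentered inputs by default; `center_inputs=True`
recenters g and m first, which changes what the main effects estimate
(effects at the sample means rather than at g = 0, m = 0) but not the
interaction p-value. Constant or collinear inputs yield a degenerate
result (p = 1, warning) rather than an exception so scans never abort.

## Synthetic-data generator

The generator produces the study conditions every validation study runs
under: n = 111 independent individuals (the simulated-data analysis
scale; n = 150 is used for the concordance study, the real-data scale),
10 ROIs on separate chromosomes with five CpGs at offsets
−12, −2.5, 0, +2.5, +12 kbp around the anchor — so the ±0/±3/±15 kbp
windows contain 1, 3, and 5 markers — and one SNP 500 bp from the
anchor in each of the 5 causal ROIs.

* **Methylation.** Pre-treatment beta values are Beta(μc, (1−μ)c) with
  mean μ = 0.75 and concentration c = 5; post-treatment values add
  Gaussian noise on the logit scale (SD 0.3), multiplied by the
  variance-inflation factor 3 at the 10 anchor CpGs (the designated
  high-variability treatment-response sites). The logit-scale
  perturbation keeps values in (0, 1) without truncation artifacts. The
  fairly high methylation mean reflects hypermethylated gene-body
  candidate regions and creates the regime of interest: SNP effects
  that are mostly attenuated away marginally yet recoverable through
  the interaction model.
* **Genotypes.** Independent Hardy–Weinberg dosages Binomial(2, MAF)
  with MAF 0.3; configurable in [0.05, 0.5].
* **Phenotype.** post-lnTG = 0.5 + 0.8·pre-lnTG + 0.002·age +
  Σⱼ βⱼ gⱼ(1 − mⱼ) + ε, ε ~ N(0, 0.35²), with mⱼ the individual's
  post-treatment methylation at the causal SNP's anchor CpG. The linear
  (1 − m) attenuation is anchored by its two limits — full effect at
  m = 0, none at m = 1 — with the intermediate shape a package choice.
* **Effect sizes.** Target heritabilities (0.10, 0.07, 0.05, 0.03,
  0.01), strictly decreasing across the causal ROIs, are package
  defaults. hⱼ is defined against the covariate-adjusted phenotypic
  variance σ²_T = σ²_ε/(1 − Σh): βⱼ = √(hⱼσ²_T / Var(g(1 − m))), where
  Var(g(1 − m)) is evaluated by deterministic quadrature (Beta quantile
  midpoints × Gauss–Hermite nodes) against the configured genotype and
  inflated-methylation distributions, so "decreasing heritability" is
  well defined marginally. The all-zero heritability tuple is the
  designated null configuration used for calibration studies.

What the generator does **not** emulate: pedigree/family structure and
polygenic background (the analyses target independent individuals),
linkage disequilibrium between SNPs, spatial correlation of methylation
along a region, batch or cell-composition structure in beta values, and
direct CpG main effects on the phenotype. Passing calibration and power
checks on these data therefore demonstrates the statistical machinery
under clean, independent-marker conditions, not robustness to the
correlation structure of real cohort data.

## Validation studies and their tolerances

All studies are seeded and live in `roikst.validation`; the acceptance
script and the test suite run the same code.

* Mixture-tail accuracy: χ²₁/χ²₂ anchors at their 0.05 quantiles to
  ±1e-4; 25 random spectra (k ≤ 10, weights U(0.2, 3), thresholds
  mean + U(0.5, 2.5)·SD) against 10⁶-draw Monte-Carlo tails within 3 MC
  SEs.
* Permutation agreement: 20 null datasets (n = 50, m cycling 1/3/8),
  10⁴ permutations, analytic p within 3 binomial SEs.
* Type-I error: 5000 zero-effect replicates at n = 111, testing ROI-1's
  ±3 kbp window; rejection rate at α = 0.05 inside the exact binomial
  99% band, KS uniformity at the 1% level.
* Concordance: 200 null datasets at n = 150, m = 1; Spearman ρ between
  kernel and regression p-values > 0.99 (measured: 1.0, as the two are
  analytically equivalent here).
* Interaction recovery: one n = 500 replicate; (β̂₁, β̂₁₂) within 3 SEs
  of (β, −β).
* Power: 1000 paired replicates at n = 111 (each replicate analyses all
  five causal ROIs of one dataset, keeping the curves comparable);
  the interaction model's SNP test must beat the SNP-only regression at
  the top heritability, and its power must be non-increasing across the
  decreasing-heritability ROIs. Typical values:
  interaction ≈ (0.65, 0.51, 0.38, 0.24, 0.11) vs SNP-only ≈ 0.59 at
  the top ROI.

Replicate counts were chosen so the full validation pass takes about a
minute on one CPU while keeping the binomial/KS tolerances meaningful.

## Known limitations

Linear kernel only (no IBS/polynomial/Gaussian kernels); continuous
phenotypes only; no family random effects or kinship adjustment; no
small-sample moment corrections beyond the exact ratio tail; VCF input
is a read-only convenience restricted to biallelic records; genome-build
conversion and probe-level methylation preprocessing are out of scope —
beta values are taken as given.
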