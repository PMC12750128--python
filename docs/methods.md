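# Methods

## Model

`hybridgp` fits multi-kernel Bayesian random-effects regressions for
line-level breeding values.  The response is a BLUE (design-adjusted line
mean) per line and environment:

    y_ij = mu + sum_k u_k[j] + eps_ij,
    u_k ~ N(0, sigma_k^2 K_k),     eps_ij ~ N(0, sigma^2),

where j indexes lines, i indexes environments (treated as replications —
no genotype-by-environment interaction term), and each K_k is a J x J
kernel over lines.  Eight registered models differ only in their kernel
lists:

| model | kernels | description |
|-------|---------|-------------|
| M1 | G | linear genomic (VanRaden), G = XX'/p |
| M2 | H | linear phenomic, H = UU'/3 |
| M3 | K | Gaussian genomic |
| M4 | H, K | additive linear-phenomic + Gaussian-genomic |
| M5 | K_H, K | additive Gaussian-phenomic + Gaussian-genomic |
| M6 | H, K, K_CC, K_PP | M4 plus hybrids from the product H x K |
| M7 | H, K, K_CCH, K_PPH | hybrids from K_H x K, linear phenomic head |
| M8 | K_H, K, K_CCH, K_PPH | all-Gaussian with hybrid terms |

X is the column-standardised SNP matrix (0/1/2 coding), U the
column-standardised matrix of the three vegetation indices (NDVI, NDRE1,
Can_Cover).  Gaussian kernels use exp(-||x_j - x_k||^2 / sigma^2) with the
median heuristic: sigma^2 is the median of the J(J-1)/2 off-diagonal
pairwise squared distances.  Self-distances are excluded because they are
identically zero and would bias the bandwidth downward.

### Hybrid triangular-product kernels

For two source kernels KA, KB the ordinary matrix product M = KA.KB is
generally asymmetric.  The two hybrid kernels symmetrise its triangles:

    K_upper = UT + UT',   K_lower = LT + LT',

where UT is the strict upper triangle of M plus half of diag(M) and LT the
strict lower triangle plus the other half.  The half-diagonal convention is
a deliberate design choice: it makes both kernels symmetric with identical
diagonals and gives the exact reconstruction identity
`K_upper + K_lower = M + M'`, which the test suite asserts to 1e-12.  An
alternative "diagonal wholly in the upper part" convention is selectable in
the kernel settings.  Because the triangular construction does not
guarantee positive semidefiniteness, hybrid kernels are eigenvalue-clipped
to the PSD cone by default (`psd_repair`, floor 0); the repair is recorded
in the kernel's provenance so its effect is auditable.

## Gibbs sampler

Each kernel effect is sampled in its eigenbasis (K = Phi Lambda Phi',
u = Phi delta; eigenvalues <= 1e-10 dropped, constraining the effect to the
kernel's column space).  When every line has the same number of
observations the conditional precision of delta is diagonal and updates are
O(J) per kernel after a single O(J^3) eigendecomposition; unbalanced
multi-environment data fall back to an m x m Cholesky per kernel per sweep.
Variance components have scaled-inverse-chi-squared full conditionals with
df0 = 5 and scales S0_k = Var(y) R2 / n_kernels (df0+2) / mean(diag K_k),
R2 = 0.5 split equally across kernels — the convention of the standard
Bayesian genomic-regression software this model family is usually fitted
with.  The intercept has a flat prior.  Masked (test) responses are latent:
they are redrawn each sweep from their conditional normal, and the reported
prediction for a masked cell is the posterior mean of its *fitted value*
mu + sum_k u_k[j] over retained samples — same expectation as averaging the
noisy imputed draws, with far lower Monte Carlo variance.

Defaults: 6000 iterations, 1000 burn-in, thinning 5.  Chains are
bit-reproducible given the seed.  Effective sample sizes of all variance
components (initial-positive-sequence estimator) are reported as chain
diagnostics.  The closed-form single-kernel mixed-model (kriging) solution
is kept in the package only as an independent test oracle
(`blup_oracle`); the test pins the intercept at the sample mean so the
oracle's (y - ybar) centering is matched exactly.

## Cross-validation and metrics

CV1 ("untested lines in tested environments") masks entire lines: all
observations of a test line, in every environment, are held out.  The
driver draws five independent seeded 80/20 splits of the line set (random
partitions, not folds).  On each masked set it computes Pearson
correlation, NRMSE (RMSE over the mean of the observed values), and PM_10
/ PM_20 — the percentage of the true top 10%/20% of lines recovered in the
predicted top set, top-set size ceil(f n), ties broken by stable input
order, larger-is-better by default with a per-trait flip.  Relative
efficiency compares the per-metric best model (max for COR/PM, min for
NRMSE) with each other model: (best/other - 1) x 100 for COR/PM and
(other/best - 1) x 100 for NRMSE, so a positive value always quantifies
the other model's shortfall.  Undefined metrics (e.g. zero variance in a
tiny test set) are excluded from averages with a log line rather than
propagated.

## Marker and spectral preprocessing

SNP QC applies four rules verbatim and configurably: missing fraction
<= 0.5, allele-based MAF >= 0.05, heterozygote fraction <= 0.05, and
homozygote fraction <= 0.80.  Note the last two are jointly near-exclusive
for fully homozygous inbred panels (a SNP with zero heterozygotes has
homozygosity 1.0); the thresholds are therefore explicit arguments and the
filter report counts removals per rule so the consequence is visible.  MAF
is allele-based, (2 n_hom_alt + n_het) / (2 n_called).  Imputation is
column-mean or a deterministic low-rank EM (mean-fill, truncated SVD
reconstruction at the rank capturing >= 90% variance, overwrite missing
cells only, iterate to 1e-4); observed calls are never altered and imputed
values are clipped to [0, 2].  Standardisation uses the population SD
(divide by J), which makes the mean diagonal of G = XX'/p exactly 1 — the
kernel-scale checks in the tests are exact because of this choice.

Radiometric calibration is the fitted linear map SR = DN x slope +
intercept (the intercept carries its own sign, as a regression fit
produces).  When no NIR calibration panel exists, NIR is estimated from the
visible bands as 2.921 Blue - 0.754 Red; an optional multiplicative
correction factor (3.07) can be applied to that estimate but is off by
default because its point of entry into the pipeline is a convention, not
a derivation.  GNDVI is (NIR - Green)/(NIR + Green), its standard
literature definition; Can_Cover is the mean GNDVI over a plot's subplots
(N = 1 at plot level, the contract here).

## Synthetic data

The generator emulates a winter-wheat breeding trial at desk scale:

- **Markers**: per-SNP allele frequency uniform in (0.05, 0.5], genotypes
  Binomial(2, f) — Hardy-Weinberg, unlinked.  No LD, no pedigree, no
  inbreeding; consequently the default QC heterozygosity rule (tuned to
  inbred panels) must be loosened for simulated data, and kernel eigenvalue
  spectra are flatter than real panels'.
- **Genetic values**: infinitesimal model g = X beta, beta iid normal
  scaled so Var(g) equals sigma_g^2 = h2 residual_sd^2/(1 - h2).
- **Phenomics**: three index columns, each phenomic_loading x
  standardize(g) plus independent noise, affinely mapped into plausible
  index ranges (NDVI around 0.65, NDRE1 around 0.35, Can_Cover around
  0.55), so corr(index, g) is the loading by construction.
- **Phenotypes**: Y = mu + g_j + e_env + eps with environment shifts only
  (no GxE), and a sparsity fraction of line x environment cells observed —
  default 0.5 with two environments, matching the "each line in one of two
  environments" structure of the emulated trials.

Defaults are J = 300, p = 1000, h2 = 0.5, loading = 0.6, residual SD 1,
environment-effect SD 0.25, mu = 5 (yield-like scale, t/ha).  Because the
indices are simulated directly at line level, passing tests demonstrate the
statistical machinery, not UAV image processing; and because markers are
unlinked, absolute genomic prediction accuracies are lower than real wheat
panels at the same J.

### Problem sizes in the checks

The variance-component recovery check simulates p = 150 SNPs for J = 300
lines.  With p < J the genomic kernel has a null space, from which the
residual variance is directly identified — emulating the low effective
marker dimension that LD induces in real panels.  With p >> J unlinked
simulated markers the kernel's eigenvalues concentrate near 1 and
sigma_g^2/sigma^2 is weakly identified at any J, which is a property of
that (unrealistic) design, not of the sampler.  The sampler-versus-BLUP
oracle check runs J = 100 with 20,000 sweeps; the directional CV1 check
runs J = 300, five partitions, single environment.

## Known limitations

- No GxE kernels (Hadamard or otherwise), no multi-trait models, no
  REML/frequentist path, no CV2/sparse-testing schemes.
- PSD repair changes hybrid-kernel entries slightly whenever the product
  has negative eigenvalues; variance components absorb kernel scale, so no
  rescaling is applied after repair.
- PM_20 >= PM_10 is not guaranteed and not asserted; top-set membership is
  invariant under strictly monotone transforms of predictions, which is
  asserted instead.
- The EM imputation is a deterministic low-rank surrogate with a stated
  rank rule; it is not a reimplementation of any specific package's EM.
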