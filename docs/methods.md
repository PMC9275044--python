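# Methods

## Model

For n animals and t traits the phenotype matrix `y` (n×t) follows

```
y = x mu' + a + e,    vec(a) ~ N(0, G0 ⊗ A),    vec(e) ~ N(0, R0 ⊗ I),
```

with `x` the intercept covariate (ones in the natural basis), `A` the
genomic relationship matrix, and `G0`, `R0` the t×t genetic and
residual covariances.  Records are assumed complete: every animal has
either all traits observed or none (the withheld test animals).  Fixed
effects beyond the per-trait intercept are out of scope; phenotypes are
assumed pre-adjusted.

All Kronecker-structured draws and reconstructions use the matrix
identity `a = L_A Z B'` (Z iid standard normal, `B B' = G0`,
`L_A L_A' = A`), which realizes `cov(vec a) = G0 ⊗ A` without ever
forming an nt×nt matrix.  The orientation (right-multiplication by `B'`)
is fixed by this covariance requirement and verified by a Monte-Carlo
oracle against the explicit Kronecker product.

## Non-centered parameterization and priors

The NUTS target is parameterized on an unconstrained vector

```
[ vec(Z) | log sd_a | log sd_e | w_a | w_e | mu ]
```

where each `w` block maps to a correlation Cholesky factor through the
canonical-partial-correlation transform (tanh, then row
normalization).  Standard deviations and correlations are separated
(`G0 = Λ_A Ω_A Λ_A`), so the two prior families are:

* **LKJ**: `Ω ~ LKJ(η)` expressed on the Cholesky factor
  (`Σᵢ (t−i+2η−2) log L_ii`, rows i ≥ 2) and half-Cauchy(0, 5) on each
  standard deviation.  η defaults to 1 (uniform over correlation
  matrices); the η-sensitivity grid {0.25, 0.5, 1, 2, 4} is available
  in the experiment runner.
* **Inverse-Wishart**: density `|C|^{-(v+t+1)/2} exp(−tr(C⁻¹S⁻¹)/2)` on
  the *assembled* covariance, transported to the unconstrained
  coordinates with the exact factorization Jacobian.  The determinant
  and Jacobian terms collapse to linear functions of `log sd` and of
  `log(1−z²)` over the partial correlations z (coefficients `−v` and
  `−(v+k+1)/2` for 0-based column k), which was verified numerically
  against `scipy.stats.invwishart` plus a finite-difference Jacobian.
  Defaults `S = I`, `v = t`, matching the Gibbs sampler so the two
  samplers share one posterior — the basis of the cross-sampler
  agreement test.

All transform Jacobians are included, so the density is proper on the
unconstrained space.  Gradients are exact (hand-derived reverse-mode
accumulation through the factor construction); central finite
differences are the acceptance contract for them.  Points where
`exp(log sd)` over/underflows or tanh saturates report `−inf` and are
handled by the sampler as divergences.

## Samplers

**NUTS** implements the slice-variant recursive-doubling algorithm:
trajectories double until a U-turn (inner product of momentum with the
end-to-end position difference non-positive), a divergence
(per-leapfrog energy error exceeding 1000), the depth limit (10) or the
leapfrog budget (1000).  Step size adapts by Nesterov dual averaging
(γ = 0.05, t₀ = 10, κ = 0.75, target acceptance 0.8) from a
double/halve initialization.  A diagonal metric is estimated during
warm-up: draws from the second warm-up quarter give per-coordinate
variances (shrunk toward unit scale), the metric switches in at
mid-warm-up and the step size is re-initialized and re-adapted on the
new scale.  The non-centered innovations are already unit-scale, but
the global coordinates (log standard deviations, correlations,
intercepts) have heterogeneous posterior widths — some contracting as
1/√n, others O(1) when a trait's heritability is weakly identified —
and the estimated metric is what keeps trajectories short (~30 leapfrog
steps, tree depth ~5 on the study posterior) without biasing slow
coordinates.  A fixed identity or user-supplied diagonal mass remains
available (`adapt_metric=False`, `mass_diag`).  Default run length:
2000 iterations, first 1000 discarded as warm-up.

**Gibbs** cycles (mu, a) → G0 → R0 with inverse-Wishart conditionals
`G0 | a ~ IW(v_A+n, S_A⁻¹+a'A⁻¹a)` and `R0 | e ~ IW(v_E+n, S_E⁻¹+e'e)`.
The location block is drawn *jointly* from the mixed-model-equation
conditional.  Default single chain of 10,000 iterations, 1000 burn-in,
thinning 10 (900 kept draws).

**Eigenbasis computation.**  Both samplers work in the eigenbasis of
`A = U D U'`.  The rotation is orthogonal and the model supports an
arbitrary intercept covariate (`x = U'1`), so the posterior is
untouched while `chol(A)` becomes diagonal: the NUTS gradient costs
O(nt) per leapfrog instead of O(n²t), and the Gibbs location draw
factorizes into n independent t-variate normals behind a t×t Schur
complement for mu — algebraically the same joint draw as a dense
Cholesky of the mixed-model coefficient matrix, which remains the test
oracle.  Eigenvalues are floored at 1e-8 of their mean, mirroring the
escalating diagonal jitter (0 → 1e-10 → 1e-8 → 1e-6 of mean diag) used
for direct Cholesky factorization of near-singular kinships (synthetic
panels with fewer SNPs than animals are rank-deficient).

## Synthetic data

The genotype generator emulates the role of a commercial pig nucleus
line panel: per-SNP allele frequencies Uniform(0.05, 0.5), ~30,000 SNPs
at full scale, and full-sib families (default size 5, gene-dropped from
simulated parents) so the GRM has strong off-diagonal blocks (~0.5
within families).  It does **not** model linkage disequilibrium,
selection, or multi-generation pedigrees; passing tests therefore show
parameter recovery under the set (co)variances and a realistic
relatedness spectrum, not robustness to real LD structure.  The
simulation truth is `G0 = [[1.0, 0.67], [0.67, 5.0]]`,
`R0 = [[9.0, 0.67], [0.67, 5.0]]` (heritabilities 0.1/0.5, genetic
correlation ≈0.30, residual correlation ≈0.10).  Scenario 1 uses 2314
animals (2000 train / 314 test), scenario 2 uses 578 (500/78); a scale
factor shrinks animals and SNPs proportionally for desk-scale runs
(SNP floor 500).  The train/test split is uniformly random (the
synthetic population has no generation structure to select a "last
generation" from).

## Evaluation

RMSE and MAE aggregate posterior-mean point estimates against the *set*
truth over replicates; relative versions divide by the NUTS-LKJ value
so the baseline is exactly 1.0.  Derived parameters (h², correlations)
are computed per draw and then averaged.  Variance-component tables are
fitted on the full scenario population; the train/test split is used
only for the breeding-value study, where test EBVs come from kinship
regression `a_test = A_ts A_tt⁻¹ â_train` — identical to the posterior
mean of test-animal effects kept inside the model with missing records,
because the conditional mean under `G0 ⊗ A` is trait-wise kinship
regression (G0 cancels).

## Diagnostics

Gelman–Rubin R̂ is the classic (non-split) potential scale reduction
from three parallel chains, flagged above 1.1.  The Geweke z-score
compares the first 10% and last 50% window means using
spectral-density-at-zero variance estimates: Bartlett-windowed
autocovariances with lag budget `min(0.1·window, 1.5·√window)` and a
white-noise equivalent-degrees-of-freedom correction.  The 10% lag rule
alone makes the estimator noisy and biased low in short windows
(|z| > 1.96 on ~8% of iid chains); the capped budget plus correction
calibrates coverage to ~94–95%, which the calibration test asserts at
95% ± 2%.  Strongly autocorrelated chains remain somewhat
anti-conservative, as with any windowed estimator.

## Problem sizes and numerical choices

The acceptance workflow runs scenario 1 scaled to 500 animals
(5 replicates, NUTS 1000 + 1000, Gibbs 10,000) and scenario 2 at its
full 578 animals (3 replicates), with ~6,500 and 30,000 SNPs
respectively — sizes chosen so a complete replication fits comfortably
on a single CPU while the parameter-recovery quantities stay within
their Monte-Carlo bands.  Replicate seeds are `seed + replicate`; fits
derive per-method offsets from that, so every run is reproducible draw
for draw.  Ties and degenerate inputs: monomorphic SNPs abort GRM
construction with the SNP named; an all-missing SNP is removed by the
call-rate rule before any division; zero-variance chains and windows
raise explicit diagnostic errors rather than returning NaN.

## Known limitations

* No REML estimator (the study's REML column came from external
  software); no real-data loaders beyond plain-text/PLINK-raw dialects.
* The warm-up metric estimate uses a single window; posteriors whose
  scales change drastically after mid-warm-up would need the longer
  windowed schedules of production samplers.
* Missing trait records (beyond fully withheld test animals) are not
  supported; the likelihood requires complete rows.
* The Gibbs sampler here is a well-mixing joint-block implementation;
  published single-site samplers can show convergence artifacts this
  implementation does not replicate.
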