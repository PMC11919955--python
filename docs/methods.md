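# Methods

This note records the models implemented in `pevsim`, the numerical
choices behind them, the study conditions embedded in the synthetic data
generator, and what the test suite does and does not establish.

## Two-stage variance estimation

**Stage 1** fits the fixed-effects model

    y = location + block(location) + genotype + ε,

with residuals i.i.d. within each location but heterogeneous across
locations, by iterated feasible generalized least squares: OLS, then
per-location residual variances from the weighted residual sums of
squares (degrees of freedom apportioned by the trace of the weighted hat
matrix restricted to each location's rows), then re-weighted GLS,
iterated to a relative change below 1e-8.  Genotype BLUEs are reported as
centered effects so the stage-2 model needs only an intercept.  A
rank-deficient design raises an identifiability error naming the aliased
columns (from a pivoted QR); a zero per-location residual variance is
flagged as degenerate rather than silently floored.

**Stage 2** is the single-kernel model `ĝ = 1μ + a + ε` with
`a ~ MVN(0, K σ²ₐ*)`.  REML is exact: the response is rotated onto the
eigenbasis of K, the restricted likelihood is profiled over the variance
ratio λ = σ²ₐ*/σ²ε, and λ is found as the root of the analytic REML score
(Brent's method on log₁₀ λ, bracketed by an 81-point grid scan over
[1e−10, 1e10]) with the λ = 0 boundary always evaluated and compared.
The score-root formulation matters: near the optimum the profiled
likelihood is flat to machine precision in λ, and a direct minimizer
leaves ~1e-8 relative indeterminacy that breaks the exact scaling
identity σ̂²ₐ*(cK) = σ̂²ₐ*(K)/c.  Singular kernels (the VanRaden G always
is) need no special handling on the eigenbasis.  A kernel proportional to
the identity makes the decomposition unidentifiable; the fit returns the
boundary solution with the total variance preserved and warns.

**BLUPs and PEV** come from the P-matrix form of Henderson's mixed-model
equations: with `V = K σ²ₐ* + I σ²ε` and `P = V⁻¹ − V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹`,

    â   = σ²ₐ* K P y,
    PEV = σ²ₐ* K − σ²ₐ*² K P K,

which equals the random-effect block of the inverse MME coefficient
matrix without ever forming K⁻¹.  BLUPs are reported mean-centered.  Note
that the raw MME PEV retains one unit of prior uncertainty about the
effect mean (an `11ᵀ/n` component confounded with the intercept); it
vanishes from the PEV of the *centered* effects, which is the relevant
quantity in the no-noise limit.  The PEV-corrected estimator itself uses
the raw trace, `Σ âᵢ²/n + tr(PEV)/n`, with the n (not n−1) denominator
because the BLUP mean is known to be zero.

**Multi-location model.**  The model
`y = location + block(location) + a + aL + ε` with `a ~ MVN(0, G σ²ₐ*)`,
independent per-location interaction deviations
`aL_l ~ MVN(0, G σ²_aL,l*)` and per-location residual variances is fitted
by EM-REML with average-information (AI) acceleration.  Each G-structured
effect is reparametrized on the eigenbasis of G (effects live in the
range of G; the effective level count is rank(G)), which keeps EM valid
for singular G.  AI steps use step-halving and are accepted only if the
restricted likelihood does not decrease; EM otherwise.  Because EM
approaches zero boundaries geometrically slowly, an active-set rule runs
every 10 iterations: a small component with a negative REML score is
frozen at zero when the likelihood is indifferent to doing so, and halved
when that improves the likelihood.  Variance components are constrained
non-negative by truncation.  Convergence is a maximum parameter change
below 1e-8 relative (with an absolute floor of 1e-4·var(y) in the
denominator so boundary-pinned components cannot stall the criterion); a
plateaued solution at the iteration cap is accepted if parameters moved
less than 1e-4·var(y) in the last step.  Under a true-zero interaction
the REML optimum is genuinely interior (small positive) in a minority of
datasets at moderate size — the tests therefore assert that the
interaction scaler collapses to a negligible share of the additive
scaler, not that it is exactly zero in every repetition.

**Estimators.**  `vanraden` and `gn` read the REML scaler off fits with
K = G and K = GN respectively; `m2` is βᵀΣ_M β with β backsolved from the
BLUPs as `β = Zᵀ(ZZᵀ)⁺â` and Σ_M the marker covariance (n−1 denominator,
computed on demand with a memory warning above 20 000 markers); `pev` is
the corrected estimator above; the `unbiased` reference is
`var(ĝ) − σ̂²ε` (n−1 denominator), kept when negative and flagged.  When
phenotype subsets drop genotypes, the backsolve uses the panel-centered
marker rows of the retained genotypes (their Gram matrix is, up to the
VanRaden denominator, exactly the subset G, so `Zβ` reproduces `â` and
the identity m2 = n/(n−1) · var(â) stays exact), while Σ_M re-centers
within the subset as a sample covariance must.

## Generalized SEM, SEV and effective sample sizes

Implemented exactly as stated in the README; numerical notes:

- `1ᵀΣ1` may be a tiny negative number for numerically semidefinite Σ and
  is clipped at zero; a row-sum-zero Σ (any VanRaden G) gives SEM = 0
  exactly and an undefined ESS for the mean (returned as NaN).
- Perfect correlation gives SEV = 0 and an infinite variance-ESS
  (returned as `inf`); sentinels rather than exceptions, because scenario
  tables must tabulate these limits.
- Monte-Carlo sampling uses an eigendecomposition square root so
  semidefinite covariances (relationship matrices, the all-ones limit)
  are sampleable; empirical SEM/SEV are the standard deviations of
  per-draw sample means and sample variances, and their own Monte-Carlo
  standard errors are estimated by batching (25 batches by default —
  enough degrees of freedom that a "within k batch-SEs" comparison is not
  dominated by the noise of the SE estimate itself).

## Simulation strategies

All three simulate a balanced multi-location RCBD with terms
location, block-within-location, additive, additive-by-location and
residual; phenotypes are the exact sum of the mapped effects, and sample
statistics use the n−1 denominator throughout.  Kronecker-structured
interaction effects are ordered genotype-fastest within location.

- **MVN** draws every term from its nominal distribution
  (`a ~ MVN(0, G σ²ₐ*)` etc.).  The expected realized sample variance of
  a correlated term is `tr(Σ_c)/(n−1)` (Σ_c the double-centered
  covariance), not the nominal scaler — the quantitative statement of why
  unscaled draws miss their targets.
- **Fixed** builds effects at the marker level: 2500 QTL drawn uniformly
  without replacement from the marker panel (markers act as QTL for a
  single-trial simulation), effect magnitudes from Γ(shape 0.4,
  scale 1.66) with independent fair signs, additive values a = Mβ, the
  interaction matrix `AxL* = M_a B_aL L_cov` from 100 environmental
  covariates drawn from MVN(0, K_e) and standard-normal interaction
  intensities, then double-centered; location main effects are the
  column means of the raw AxL*.  Every term is rescaled so its realized
  standard deviation equals the target exactly.
- **ESS** replaces each fixed target with a draw
  `s² ~ Γ(mean = σ², sd = SEV)`: the additive SEV uses Σ = GN σ²ₐ (the
  unit trace mean makes the trace-mean variance equal the target), the
  location SEV uses Σ = K_e σ²_L, the interaction SEV uses
  Σ = (K_e ⊗ GN) σ²_aL with one shared draw (one overall interaction
  target exists), and the i.i.d. block and residual terms use the
  classical formula with one independent draw per location (n = blocks
  per location and plots per location respectively) — heterogeneous
  per-location variances being the realistic behaviour.  A term with
  SEV = 0 (perfect correlation or a zero target) falls back to the Fixed
  behaviour with a warning.

The deviation report standardizes the mean realized variance over R
repetitions as `(mean − target)/(SEV/√R)`, treating per-rep variances as
independent draws with standard deviation SEV; for terms whose per-rep
value averages L independent per-location variances the SEV is divided
by √L.  This normal approximation to the distribution of the average is
the package's own modelling choice.  Under it the ESS deviations are
empirically well calibrated (mean ≈ 0, sd ≈ 1 per term across seeds), so
a band check at ±2 retains the usual ~5% per-term false-alarm rate: an
occasional out-of-band term under a fresh seed is expected behaviour,
not a regression.

## Synthetic genotypes and ground truth

Marker panels are generated from latent Gaussian haplotypes: within
blocks of `ld_block_size` loci (default 20) the latent values follow an
AR1 process with correlation `ld_decay` (default 0.9), thresholded at
the allele frequency (a Gaussian copula) — the simplest mechanism that
produces the blocked marker covariance driving the G-scaling problem.
Population structure comes from subpopulation allele frequencies
scattered with standard deviation `divergence` (default 0.15) around a
common base frequency drawn uniformly in [0.1, 0.9]; heterozygosity is
controlled by an inbreeding mixture (`inbreeding = 1`, the default,
makes both haplotypes identical — a fully inbred, structured panel;
`inbreeding = 0` gives Hardy–Weinberg proportions).  Defaults emulate an
inbred small-grain panel; an outbred conifer-like panel is one argument
away.

Ground-truthed trials reuse the Fixed machinery, so the recorded per-term
variances are exact.  The estimator-validation conditions are: 200
genotypes × 500 markers, two locations × three blocks, σ²_L = 1,
σ²_Block = 0.25, σ²ₐ = 1, σ²_aL = 0.25, and plot residual variance 6 so
that the genotype-mean error variance equals σ²ₐ (entry-mean
heritability 0.5 — a deliberately noisy, realistic regime).  Each
repetition draws a fresh population and trait architecture.  A
double-centered interaction contributes nothing to genotype means in a
balanced design, so the stage-1/stage-2 chain remains correctly
specified; under 75% subsampling it leaks into the residual, as it would
in practice.

Because the VanRaden G built from column-centered markers has zero row
sums, the trace-normalized GN is *on average* correctly scaled over
exchangeable trait architectures: its error is trait-specific, large in
magnitude but nearly symmetric in sign across random architectures.  The
benchmarks therefore rank estimators by their per-repetition error
against the unbiased reference (mean deviation and RMSE), the metric
under which the PEV correction is consistently two orders of magnitude
more accurate, rather than by a sign-averaged bias that would wash out
GN's trait-level failures.

## Problem sizes and defaults

Test-suite and acceptance-script runs use desk-scale sizes chosen once:
50–200 genotypes, 120–500 markers, 10⁴–10⁵ Monte-Carlo samples, 50
balanced / 20 unbalanced estimator repetitions and 100 simulation
repetitions per strategy.  The trial design defaults (50 genotypes, 5
locations, 3 blocks, location correlation 0.3) are a typical small
multi-environment trial.  Larger runs only sharpen the Monte-Carlo
comparisons; nothing in the methods depends on size.

## Limitations

- Diploid dosages only; no ploidy > 2, no dominance or epistasis
  construction (a user-supplied dominance matrix can be consumed as a
  custom covariance), no NOIA-style matrices, no imputation or marker QC
  beyond range checks.
- Single-trial simulation: markers act as QTL; no recombination or
  multi-generation dynamics.
- The synthetic generator does not model coalescent realism, mutation,
  pedigrees, or spatial field trends; passing tests demonstrate correct
  behaviour under its copula-LD, mixture-inbreeding world, not under
  every real crop dataset.
- The stage-1/stage-2 pipeline assumes the stage-1 BLUE errors are
  approximately i.i.d. within the stage-2 model; severe unbalance makes
  both the reference and all estimators noisy (their agreement, not
  their individual stability, is the validated property).
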