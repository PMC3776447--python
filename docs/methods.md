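# Methods

## Model and hypothesis

Expression values in a gene set are modeled jointly:

    Y_ij = α_j + x_i β_j + ε_ij,   i = 1..n subjects, j = 1..p genes,

with error vectors ε_i independent across subjects and multivariate normal
with mean 0 and true covariance Σ. `x` is a single sample-level variable —
binary (e.g. case/control, coded 0/1 with at least two samples per group)
or numeric. The set-level null is β = 0. Because a p-degree-of-freedom test
loses power when p is large and many genes are null, the β_j are treated as
draws from a common distribution with mean 0 and variance τ, making the
null the one-dimensional variance-component hypothesis τ = 0. The score
statistic for τ under a working covariance V for ε_i is a quadratic form in
the data; working independence (V = I) recovers the global test, and the
statistic with V = Σ is the optimal member of the family (usable in
simulations, unknowable in practice).

Assumptions worth stating: samples are exchangeable under the null (the
permutation basis), errors are Gaussian for the theoretical moments and the
mixture-of-chi-squares law (the permutation p-value does not need
Gaussianity), and a single phenotype is tested (no multi-class support).
Nuisance covariates can be removed beforehand by per-gene ridge
residualization (`adjust_for_covariates`; intercept unpenalized, OLS when
the penalty is 0).

## Computing the statistic

The stacked form of the statistic involves np×np matrices; block algebra
reduces it exactly to

    Q = ‖V⁻¹ s‖²,   s = Σᵢ (xᵢ − x̄)(Yᵢ − Ȳ),

computed via one Cholesky factorization of V and a triangular solve —
O(p³ + np) per evaluation, with the factorization reused where possible.
Under the null the GLS intercept estimate collapses to the per-gene sample
mean for any V, so centering is covariance-free. For binary x the
closed-form equivalent is Q = (n₁n₂/n)²·dᵀV⁻²d with d the difference of
group mean vectors; this equals the general form to machine precision and
is provided as a convenience (`tegs_two_group`). The test suite verifies
the reduction against a literal stacked-matrix evaluation for every shape
with n·p ≤ 60.

Under the null and Gaussian errors, s ~ N(0, cΣ) with c = Σᵢ(xᵢ − x̄)²
exactly (the finite-sample centering is absorbed into c), so Q follows a
mixture of 1-df chi-squares with weights equal to the eigenvalues of
c·V⁻¹ΣV⁻¹; the weight sum equals E₀(Q) by the trace identity. The exact
weighted-chi-square tail (Imhof integration) exists only as a test oracle,
not as a headline method.

## Working covariance estimation

All estimated structures derive from one object: per-gene OLS residuals of
Y on (1, x) — group-mean centering when x is binary — whose sample
covariance S (divisor n − 1) is stabilized as S + c·I with c the 5th
percentile of the sample variances (linear interpolation between order
statistics; percentile configurable). Then:

- `unstr` is the ridge estimator itself;
- `cpsym` replaces it with an exchangeable matrix: common covariance = mean
  off-diagonal, common variance = mean diagonal. The diagonal choice is a
  design decision (the source recipe specifies only the off-diagonal); a
  common variance makes the structure exactly exchangeable, and the
  alternative (keep per-gene variances) is easy to add. For a PSD input the
  mean off-diagonal never exceeds the mean diagonal (1ᵀS1 ≤ p·tr S), so the
  output is PD whenever the input has a ridge;
- `f2` / `f-adpt` keep the top-k eigencomponents of the ridge estimator
  (k = 2, or the smallest k explaining ≥ 80% of the eigenvalue mass,
  capped at min(p, n − 1)) and add a diagonal restoring the ridge
  estimator's diagonal exactly, floored at 1e−8 × mean diagonal so a gene
  fully captured by the factors cannot zero out. Eigendecomposition of a
  symmetric PSD matrix is used (equivalent to SVD); components are ordered
  by decreasing eigenvalue with ties left in index order, and eigenvector
  sign is irrelevant (outer products). Note the truncation-plus-diagonal
  construction does not exactly reproduce a rank-k-plus-spherical input:
  the kept eigenvalue absorbs the spherical part (relative off-diagonal
  inflation d/‖a‖²), vanishing as the idiosyncratic part shrinks.

The sample-covariance divisor is n − 1 rather than a per-gene n − 2
degrees-of-freedom correction; the ridge term dominates stability and the
simpler convention is documented so users can compare.

## Null distribution

**Permutation.** Phenotype labels are permuted; the working covariance is
re-estimated inside every permutation (V is the error covariance
conditional on x, so it must track the permuted pairing — this includes
recomputing the ridge constant). The p-value is (1 + #{Q⁽ᵇ⁾ ≥ Q}) / (B + 1)
with ties counted conservatively; it is valid by construction and never
returns 0. The implementation evaluates all B permutations in one batched
pass using the closed form S_b = (YcᵀYc − c·γ_bγ_bᵀ)/(n − 1) for the
permuted residual covariance (γ_b the per-gene slopes), verified in tests
to equal the one-permutation-at-a-time public API bit-for-bit. Reported
p-values require B ≥ 100 (configurable floor); results are bit-reproducible
given (seed, B, spec). The large-n Monte Carlo alternative for n > 100 is
deliberately not implemented.

**Scaled chi-square.** κ = Var(Q)/2E(Q) and ν = 2E(Q)²/Var(Q) from the
sample mean and unbiased variance of the permuted statistics; p is the
upper tail of χ²_ν at Q/κ. Accurate at moderate p-values with far fewer
permutations than the permutation p-value needs; its far tail (≤ 0.05%)
is anti-conservative, which the test suite reproduces.

**Normal mixture.** The per-permutation scaled-chi-square p-values (one
(κ, ν) fit from all B draws, reused — not leave-one-out) are probit
transformed after clipping to [1/(10B), 1 − 1/(10B)], and a two-component
Gaussian mixture is fitted by EM: median-split initialization plus 10
seeded random restarts, variance floor 1e−6, at most 500 iterations,
convergence when the loglik gain drops below 1e−8 relative to its
magnitude; the log-likelihood is non-decreasing by construction. The
reported p-value is the mixture's lower tail at the probit of the observed
scaled-chi-square p-value (small p ↔ very negative probit — the one-sided
direction is inferred from the tail-probability definition and documented
here). If no restart converges the fit falls back to a single normal with
a logged warning.

**FDR.** Storey q-values with π̂₀ estimated at λ = 0.5 (fixed-λ estimator),
monotonicity enforced by cumulative minimum; Benjamini–Hochberg available
as the π̂₀ = 1 special case.

## Power

Theoretical null moments E₀(Q) = c·tr(V⁻²Σ) and Var₀(Q) = 2c²·tr((V⁻²Σ)²)
give (κ, ν) by moment matching; the alternative shifts the mean by
c²·βᵀV⁻²β, the noncentrality is δ = (E_A − E₀)/κ (computed from the shift
directly so δ = 0 exactly at β = 0, and floored at 0), and power is the
upper tail of χ²_ν(δ) beyond the central 1 − α quantile. At β = 0 this
returns exactly α. Σ and V may be estimated from pilot data
(`covariances_from_pilot`); sweeps over effect scalings and sample sizes
are provided, but no solve-for-n inversion.

A calibration caveat, documented rather than reconciled: the analytic
formula approximates the test that rejects at the *theoretical*
moment-matched critical value. The actual testing procedure estimates
(κ, ν) by permutation, and under an alternative the permutation null is
stochastically inflated by the effect itself, so achieved
permutation-calibrated power runs a few points below the design value at
n = 20 (about 4–5 points at mid-range power in our measurements). The
experiment runner exposes a "theory" p-value method (fixed working
covariances only) so both quantities can be computed; the self-consistency
test checks the analytic value against the theory-calibrated empirical
power at 3 Monte Carlo standard errors and checks the direction of the gap.

## Synthetic data

The generator draws ε_i ~ N(0, Σ) by Cholesky, adds x_iβ, and fixes
x = (0,…,0,1,…,1) (intercepts are 0 without loss of generality — the
statistic is shift invariant). The covariance menu: compound symmetry
CS(ρ) with unit diagonal; AR1(r) with entries r^|j−k|; a two-factor
structure P₁P₁ᵀ + P₂P₂ᵀ + diag(u) with standard-normal factor entries
rescaled so the rank-2 part carries a `factor_share` (default 0.5) of each
unit variance on average and u floored at 0.05 (the share parameter is a
design decision — the source describes Gaussian factors without variances);
and an "unstructured fixture", the ridge-stabilized sample covariance of 34
pseudo-samples from a heterogeneous-variance three-factor model — a
synthetic stand-in reproducing the construction of a pilot-data-derived
truth without any external dataset. Signal genes occupy the leading
positions (the test is equivariant to gene order, and fixed placement eases
debugging). The effect-size index reported with experiment tables is
Σ|β_j| / σ̄² with σ̄² the mean true gene variance; the absolute value makes
the index informative for balanced ± layouts.

The multi-set benchmark embeds 20 sets (ten of 10 genes, ten of 40; 104
signal genes in the default layouts) in 500 genes. Setting 1 keeps sets
independent with a two-factor covariance inside each; settings 2–3
correlate sets {1–3, 4–6, 7–9, 11–13, 14–16, 17–19} through joint
two-factor structures of dimension 30 and 120 (seeded synthetic structures
— the pilot-data-estimated versions are not recoverable — flagged by the
scenario metadata); setting 3 appends 4500 unit-variance null genes outside
every set, drawn from an RNG stream separate from the core genes so
settings 2 and 3 with the same seed are bit-identical on all in-set genes.
Per-set analysis seeds derive from the root seed and the set name, so a
set's result is invariant to which other sets or extra genes are present —
this makes the self-contained-null property (per-set p-values unchanged
when 4500 null genes are appended) exact and testable.

What the generator does not emulate: heavy-tailed or skewed expression
noise, heteroscedastic library-size effects, batch structure, missing
values, or probe-level artifacts. Passing tests therefore certify the
statistics and their calibration under the stated Gaussian designs, not
robustness to those real-data features (the permutation p-value remains
valid under any exchangeable null, which is the main practical safeguard).

## Problem sizes used by the test and acceptance runs

Calibration experiments use 2000 null replicates with B = 500 permutations
at n = 20 (p = 10 for the six-variant comparison, p = 40 for the
ridge-unstructured cell, the latter at 1000 replicates in the test suite);
power self-consistency uses 1000 replicates; permutation-moment checks use
B = 10,000 on one dataset; the multi-set invariance check uses B = 200 for
its 20 sets. These sizes put three binomial standard errors at ±1.5
percentage points on an estimated 5% size, which is the comparison band
used throughout.

## Known limitations

- Two-class or numeric phenotypes only; no multi-class designs.
- No shrinkage-toward-target covariance estimators beyond the percentile
  ridge rule, and no sparse/graphical structures.
- The normal-mixture refinement inherits the scaled-chi-square far-tail
  anti-conservatism in part; for very small p-values with few permutations
  it is sharper than the permutation floor but should be read with care.
- Gene-level follow-up inside a significant set is limited to external
  single-gene diagnostics; no ridge-based per-gene inference is included.
- For n > 100 the permutation loop still works but a large-sample Monte
  Carlo approximation would be cheaper; it is intentionally out of scope.
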