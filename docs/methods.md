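# Methods

## Model and estimators

The data model is a two-level linear mixed model for balanced or unbalanced
long-format panels: for subject *i* with Lᵢ equally spaced occasions,

    yᵢ = Xᵢγ + Zᵢuᵢ + eᵢ,    uᵢ ~ N(0, G),   eᵢ ~ N(0, Rᵢ),

with Zᵢ = [1, zᵢ] (random intercept and random slope on the time-varying
covariate) and Xᵢ = ZᵢCᵢ = [1, z, c, c·z] (the level-2 covariate c is
required to be constant within subject).  The marginal covariance is
Σᵢ = ZᵢGZᵢ′ + Rᵢ.  Estimation is by REML; fixed effects are the GLS
estimates at the fitted covariance, and model-based standard errors are
√diag([Σᵢ Xᵢ′Σᵢ⁻¹Xᵢ]⁻¹).

Three residual models are supported:

- **ID**: Rᵢ = σ²I (independent, homoscedastic, homogeneous);
- **AR1**: Rᵢ = σ²[ρ^|t−s|], one (σ², ρ) shared by all subjects;
- **CT** (Cholesky transformation): each subject's residual process is
  modeled as a stationary AR(p) with its own parameters, estimated by exact
  Gaussian ML from the subject's own series; the data are premultiplied by
  the whitening operator Aᵢ (the inverse Cholesky factor of the scaled
  residual covariance, AᵢRᵢAᵢ′ = σ²_{w,i}I) and the ID model is fitted to
  the transformed panel.  The transformed intercept column is Aᵢ·1, consumed
  verbatim — no fresh constant column is injected in step 2.

The CT rationale is the classical equivalence of GLS and OLS on whitened
data: with the true Σ, (X′Σ⁻¹X)⁻¹X′Σ⁻¹y equals the OLS estimate computed
from (Ay, AX) because A′A ∝ Σ⁻¹.  When each subject has their own Rᵢ, no
homogeneous-R mixed model is correctly specified, but per-subject whitening
restores (approximately, since the ρᵢ are estimated) an ID residual
structure for which the standard model is correct.

## Step-1 AR estimation

The per-subject model is yᵢ = Zᵢβᵢ + eᵢ with stationary AR(p) errors.  The
likelihood is the exact Gaussian one: the first p observations enter through
the stationary distribution (for AR(1), variance σ²_w/(1−ρ²)), not a
conditional least-squares approximation.  β and σ²_w are profiled
analytically — for fixed AR coefficients, whitening reduces the problem to
OLS on (Ay, AZ) — so the numerical search runs over the AR coefficients
only.  For p = 1 the search is a bracketed scalar optimization of the
profile likelihood over ρ ∈ (−0.98, 0.98); for p ≥ 2 the coefficients are
parameterized by partial autocorrelations mapped through the Levinson-Durbin
recursion, which enforces stationarity exactly.  Estimates within 10⁻⁴ of
the ±0.98 cap are flagged per subject (the whitening operator is undefined
at |ρ| = 1).

The correction procedure's order-selection step is interpretable but not
fully prescriptive (visual inspection of residual autocorrelation), so the
default keeps p fixed at 1 — the order used throughout the simulation — and
AIC/BIC selection from OLS residuals up to a user-set maximum is available
for real data (`order_selection="bic"`).

For the simulation, the AR(1) profile likelihood is evaluated in
cross-product form: because A′A is tridiagonal, M*′M* for M = [y | 1 | z] is
a closed-form combination of three cached per-subject matrices, making one
likelihood evaluation O(1) in the series length.  All subjects are optimized
simultaneously by a vectorized bracketed golden-section search seeded from a
99-point grid.  Unit tests pin this fast path to the scalar reference
implementation.

## REML engine

The REML criterion is evaluated per subject with a low-rank (Woodbury)
identity in the two random effects: with G = ΛΛ′,

    Σᵢ⁻¹ = (1/σ²)[P⁻¹ − P⁻¹ZᵢΛ(σ²I + Λ′Zᵢ′P⁻¹ZᵢΛ)⁻¹Λ′Zᵢ′P⁻¹],

where P is the AR(1) correlation matrix (the identity for ID) whose inverse
is tridiagonal and known in closed form.  All quantities reduce to
combinations of per-subject cross-product matrices of [y | X | Z] cached at
construction, so a criterion evaluation is O(1) in L after an O(L) setup;
subjects sharing a series length are batched.  This is what makes the
72,000-fit study design tractable on one CPU.

Optimization parameterizes G/σ² by its log-Cholesky factor (diagonal on the
log scale, PSD by construction, boundary reachable) and ρ by 0.98·tanh of an
unconstrained parameter; the residual scale σ² is profiled analytically
(σ̂² = r′V⁻¹r/(n−k)), leaving 3 free parameters for ID and 4 for AR1.  The
criterion is minimized per observation by L-BFGS-B with numerical gradients
(ftol 10⁻¹³, gtol 10⁻⁸, up to three jittered restarts on failure).  The
per-observation scaling matters: with raw criterion values of order 10⁵ the
first line-search trial can land on a non-finite plateau and terminate
spuriously.  Non-finite evaluations (extreme G, catastrophic cancellation in
the quadratic form) return a smooth penalty above the first finite reference
value instead of a constant, so step-length interpolation stays informative.
Starting values are method-of-moments: pooled OLS residual variance split
equally between random-intercept variance and residual variance, and ρ
started at the pooled lag-1 autocorrelation of OLS residuals.

`loglike_reml(G, sigma2, rho)` evaluates the criterion at arbitrary
parameter points without profiling; tests verify it against a direct dense
evaluation of the REML formula (log-determinants + quadratic form +
log|X′Σ⁻¹X|) to 10⁻¹⁰, and full fits against an independent REML
implementation (statsmodels MixedLM) to ~10⁻⁴.

Only point estimates and model-based SEs are produced; no degrees-of-freedom
machinery (Satterthwaite, Kenward-Roger) is included, since the study
quantifies bias rather than coverage.

## Synthetic-data generator

Panels are generated from

    y_ti = γ₀₀ + γ₁₀z_ti + γ₀₁cᵢ + γ₁₁cᵢz_ti + u₀ᵢ + u₁ᵢz_ti + e_ti,

with z_ti, cᵢ iid N(0, 1); (u₀, u₁) bivariate normal with σ²_u0 = σ²_u1 =
0.5 and σ_u0u1 = 0.15 (correlation 0.3); all fixed effects 1; and
subject-specific AR(1) errors e_ti = ρᵢe_(t−1)i + w_ti with w ~ N(0, 1),
ρᵢ ~ U(ρ̄ − 0.3, ρ̄ + 0.3), and e₁ᵢ drawn from the stationary distribution
N(0, 1/(1−ρᵢ²)) — no burn-in is needed because the process starts in its
stationary law.  At ρ̄ = 0 individual ρᵢ are negative half the time; the
AR1 and CT estimators handle ρ̂ < 0 without special-casing.

The replicate RNG is seeded from (base seed, N, L, ρ̄, replicate), so any
single replicate is reproducible in isolation and the entire bias report is
a pure function of (grid, truth, base seed).

What the generator emulates — and what it does not: it produces Gaussian,
balanced, equally spaced panels with linear effects and AR(1) (optionally
AR(p) in the estimators, but AR(1) in the generator) residual dynamics.
Real EMA data additionally feature missed prompts, unequal and random
sampling intervals, non-Gaussian outcomes, and residual variance that may
itself vary by person (the generator holds σ²_w = 1 for everyone).  Passing
tests therefore demonstrate correctness of the estimators under the stated
data-generating process, not robustness to those further complications.
For per-subject heteroscedasticity the transform module offers
`rescale_to_unit_variance`, which divides each whitened block by its
estimated innovation SD; it is off by default because the reference study
conditions use homogeneous innovation variance.

## Bias statistics

Relative bias of a parameter is mean((θ̂ − θ)/θ)·100 across converged
replicates (relative bias is undefined and refused at θ = 0; all study
truths are nonzero).  For standard errors the yardstick is the *true*
standard error, defined analytically as √diag([Σᵢ Xᵢ′Σᵢ⁻¹Xᵢ]⁻¹) at the true
generating parameters — the true heterogeneous Σᵢ of each generated design —
computed per replicate in the same cross-product form as the engine.  SE
relative bias is mean((SE_r − trueSE_r)/trueSE_r)·100.  A Monte-Carlo
variant with the empirical SD of the estimates as yardstick is provided
(`se_relative_bias_empirical`) as a truth-free diagnostic; it is noisier by
construction (the SD of ~500 estimates carries ~3% relative error) and is
not used in the reported tables.

Non-converged fits are excluded from all bias averages and reported in the
convergence table; in the shipped study conditions all fits converge.

## Problem sizes in the test suite

The quantitative checks run the three focal conditions (20×20, 20×200,
200×20; ρ̄ = 0.6) at the study's full 500 replications, parameter-recovery
checks at N = 50, L = 50 with 100 replications, and the overall-ordering
smoke check at 50 replications over N = 20, L ∈ {50, 100, 200}, ρ̄ = 0.6 —
the cells where the ID > AR ≥ CT ordering of random-intercept-variance bias
is unambiguous.  Monte Carlo cell tolerances are the larger of 3 Monte Carlo
standard errors and 15% of the reference value, with a 3-percentage-point
floor for near-zero cells.  The full 48-condition grid is available through
`run_grid(default_grid())` or `mlmct bias-report --grid default` and takes
a few hours of CPU time.

## Known limitations

- Occasions must be equally spaced within subject; missing occasions and
  random sampling intervals are unsupported (the AR covariance and its
  Cholesky factor assume a regular lattice).
- The two-step CT estimator inherits the usual two-step caveat: with short
  series (L ≈ 20) the per-subject ρ̂ᵢ are noisy and biased toward zero, the
  whitening is imperfect, and CT can be more biased than the homogeneous
  AR(1) model.  Its advantage emerges for L ≳ 50.  No iterative alternation
  between the two steps is implemented.
- ARMA/moving-average residual structures, more than two levels, crossed
  random effects, and residual variance modeled as a function of covariates
  are out of scope.
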