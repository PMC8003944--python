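# Methods

## The process model

`zigcusum` monitors count series that are simultaneously *zero-inflated*
(structurally more zeros than a geometric or Poisson law predicts — disease
counts, defect counts, crime counts in small areas) and *autocorrelated*
(this month's count partly consists of survivors of last month's count).
The model is a first-order integer-valued autoregression with a randomized
thinning coefficient:

    X_t = a_t ∘ X_{t-1} + ε_t

where `a_t ∘ X` is binomial thinning `α ∘ X` (each of the X units survives
independently with probability α) with probability 1 − β, and 0 with
probability β. The β-mixture captures environments where the whole carryover
mechanism can switch off for a period. Innovations ε_t are chosen so that
the stationary marginal is the zero-inflated geometric ZIG(p, θ):

    P(X = 0) = p + (1 − p)/(1 + θ),
    P(X = j) = (1 − p) θ^j / (1 + θ)^{j+1},  j ≥ 1.

Closed-form consequences used throughout:

* mean μ = (1 − p) θ; variance σ² = (1 − p) θ [(1 + p) θ + 1]; the
  dispersion index σ²/μ = (1 + p) θ + 1 exceeds 1 for every valid parameter
  set, i.e. the process is always overdispersed;
* lag-1 autocorrelation ρ = α (1 − β);
* the innovation law is a three-part mixture — a point mass at 0 with
  weight p / s, a Geometric with scale θ, and a Geometric with scale α θ s,
  where s = β + p (1 − β);
* the third mixture weight is proportional to α s − p, which is positive
  exactly when the stationarity constraint p / s < α < 1 holds. Parameter
  validation is therefore strict: `ZIGParams` raises outside the
  constraint rather than clamping, because outside it the "innovation pmf"
  has a negative component and every downstream quantity is meaningless.

### Parameters

| parameter | meaning | range |
|---|---|---|
| θ | geometric scale of the marginal (≈ mean of the non-zero regime) | θ > 0 |
| p | zero-inflation weight | (0, 1) |
| α | survival probability of the thinning | (p/s, 1) |
| β | probability the carryover switches off at a step | (0, 1) |

No defaults are baked in: every analysis names its parameters. The worked
examples and the acceptance script use the grids conventional for this
chart family (θ ∈ {1, 3, 5}, p ∈ {0.1, 0.2, 0.3}, α, β ∈ {0.5, …, 0.8}) and
the case-study values (θ=2.0495, p=0.185, α=0.547, β=0.5188) fitted to a
monthly drug-crime series.

## Run-length analysis

The upper CUSUM statistic C_t = max(0, X_t − k + C_{t-1}) signals when
C_t > h. Because (X_t, C_t) is a bivariate Markov chain, the pre-signal
dynamics live on the finite control region

    CR = {(n, i) : i ∈ 0..h, n ∈ max(0, i+k−h) .. i+k}

(for the degenerate case h < k the floor row i = 0 additionally contains
every n ≤ k; the two descriptions coincide whenever h ≥ k, which covers all
practical designs). With Q the sub-stochastic within-CR transition matrix,
the first and second factorial moments of the run length solve the sparse
linear systems

    (I − Q) u⁽¹⁾ = 1,      (I − Q) u⁽²⁾ = 2 Q u⁽¹⁾,

and ARL = Σ u⁽¹⁾ π₁, SDRL² = Σ (u⁽²⁾ + u⁽¹⁾) π₁ − ARL², where π₁ is the
distribution of (X₁, C₁) induced by the stationary marginal and C₀ = c₀.

Numerical choices:

* **State order** is i ascending then n ascending — any fixed order works;
  a canonical one keeps outputs deterministic and testable.
* **Transition rows** are exact convolutions of a Binomial(i, α) pmf with
  the innovation pmf (scipy computes the binomial factors in log space, so
  rows for counts in the hundreds are overflow-free).
* **Solver**: sparse LU (`spsolve`) on CSR matrices. The largest tabulated
  design (h = 128, k = 4) has 8 891 states and solves in a few seconds;
  dense and sparse solves agree to 1e−8 on small designs (tested).
* **Immediate signals.** The classical ARL/SDRL sums range over CR only,
  ignoring the event that (X₁, C₁) already signals. That event has
  probability `escape_mass` = P(X₁ > h + k − c₀): below 1e−3 for c₀ = 0
  designs but up to ≈ 4% for head-started charts. The primary `arl`/`sdrl`
  follow the classical sums (these are the quantities the standard tables
  report); `arl_with_escape`/`sdrl_with_escape` count the event as a run of
  length 1 and are the exact expectations, matching the Monte-Carlo oracle.
* **Run-length indexing**: a run length r counts plotted points up to and
  including the signaling one, fixed jointly by agreement with the
  tabulated values and with the Monte-Carlo simulator.
* The Shewhart chart (signal when X_t > UCL) is the univariate special
  case: restrict the kernel to 0..UCL, solve (I − Q) u = 1, weight by the
  stationary marginal, count an immediate exceedance as a run of length 1.

## Chart design

`recommend_k` returns ⌈μ₀⌉ — the smallest reference value that keeps the
in-control drift of the CUSUM negative. `find_h` exploits the strict
monotonicity of ARL₀ in h: exponential bracketing then integer bisection,
returning the h minimizing |ARL₀(h) − target| (target 370 by convention),
ties toward smaller h, with cached evaluations. If even h = 1 overshoots,
(1, ARL₀(1)) is returned with a warning. Published design tables for this
chart family were evidently assembled with some hand-picking around the
target, so a deterministic rule cannot match every printed (h, k) pair;
the rule here reproduces the baseline searches used in the acceptance
checks, and the ARL₀ at any externally given (h, k) is always available
directly.

Out-of-control conditions (`apply_shift`):

* `mean_theta`: μ₁ = μ₀ + δσ₀ carried by θ alone, θ₁ = μ₁/(1 − p);
* `mean_p`: the same mean shift carried by p alone, p₁ = 1 − μ₁/θ (only
  small δ are representable, since the mean cannot exceed θ on this route);
* `corr_alpha` / `corr_beta`: additive moves of α or β, shifting
  ρ = α(1 − β) upward via α or downward-β.

All shifted parameter sets are re-validated; out-of-control ARLs use the
shifted kernel *and* the shifted stationary start with c₀ = 0 (zero-state
ARL under a persistent shift), which makes the δ = 0 column of a profile
equal ARL₀ exactly.

## Estimation

The conditional likelihood conditions on X₁ and sums log one-step
transition probabilities; 4 free parameters enter AIC/BIC.

* **CLS**: the conditional mean E[X_t | X_{t-1} = x] = ρx + μ_ε is linear,
  so an OLS regression of X_t on X_{t-1} estimates ρ = α(1 − β); (θ, p)
  come from inverting the marginal mean/variance (θ = (A+B)/2,
  p = (B−A)/(B+A) with A the sample mean and B = variance/mean − 1), which
  requires overdispersion beyond μ(1 + μ) and raises otherwise, advising
  CML. Because the conditional mean identifies only the product ρ, the
  (α, β) split is completed by a bounded one-dimensional likelihood profile
  along α = ρ̂/(1 − β) — a deliberate design choice where the moment
  equations are silent.
* **CML**: Nelder–Mead on (log θ, logit p, logit β, u), with α mapped
  through a logistic onto the interval (p/s, 1) that the stationarity
  constraint leaves open, so every iterate is a valid parameter set and no
  penalty term is needed. Multi-start (CLS start plus seeded Gaussian
  perturbations, 10 by default) guards against the mild multimodality the
  (α, β) ridge induces. Estimates with any logit coordinate beyond ±12 are
  flagged as boundary cases (`converged = False`), which is how degenerate
  inputs such as an all-zero series surface.

## Simulation

`simulate_path` draws the chain directly from its definition: a Bernoulli(β)
switch, a Binomial(x, α) thinning, and an innovation drawn by inverse-CDF on
the exact three-part mixture (component choice, then a geometric). Paths are
reproducible given a seed. `simulate_run_length` advances up to 10⁵
replicates in lock-step with vectorized draws and is the independent oracle
for the linear-algebra solves.

The synthetic generator *is* the model, so simulated data reproduce exactly
the features the charts assume: a ZIG marginal, geometric-type tails,
first-order dependence ρ = α(1 − β), time-homogeneity. Real surveillance
series can violate all of these — seasonality, trends, higher-order
dependence (the motivating crime series shows partial autocorrelation out
to lag 3), covariate-driven rates. Passing tests therefore certify the
chart machinery and the estimators *under the model*, not the adequacy of
the model for any particular data set.

## Problem sizes used by the test suite

Chosen as the package's own verification budget: exact-solve checks run the
full 16-configuration in-control grid plus every profile row asserted;
Monte-Carlo agreement uses 10⁵ replicates (3 standard errors, delta-method
SE for the SDRL comparison); simulated-moment checks use paths of 2×10⁵;
CML recovery uses 10 seeds at n = 300 and n = 2400 with 3 starts, asserting
mean estimates within 0.1 (θ, p) / 0.15 (ρ) of truth and strictly shrinking
RMSE — the statistically resolvable form of consistency at this
replication, since the bias itself sits far below Monte-Carlo noise.

## Known limitations

* For the case-study design (h = 34, k = 2) at the fitted parameters the
  exact solve gives ARL₀ = 363.44 while the commonly quoted value is
  364.44; the three companion designs at the same parameters (h = 15,
  k = 4 → 358.40; h = 12, k = 5 → 372.28; Shewhart UCL = 13 → 340.25) all
  agree exactly, pointing to a transcription slip in the quoted figure.
  The package reports its computed value.
* Only the upper one-sided CUSUM with integer (h, k, c₀) is implemented;
  no FIR variants, no steady-state ARL, no two-sided schemes.
* CLS standard errors / asymptotic inference are not provided; the profile
  completion of (α, β) can be flat when ρ̂ is small, which CML handles
  better.
* `mean_p` shifts can only represent mean increases up to θ − μ₀.
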