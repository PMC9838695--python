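# Methods

## Model

Uncontrolled (resting) dynamics are a stationary Ornstein–Uhlenbeck process
on `n` ROIs,

    dx(t) = A x(t) dt + C dw(t),        S_C := C Cᵀ ≻ 0,

with a Hurwitz drift `A` (units 1/time) and a nonsingular noise covariance
rate `S_C` (signal²/time).  Only `S_C`, never `C` itself, enters any
computation.  Brain states are Gaussian distributions; the resting state is
the stationary law `N(0, Σ_rest)` with `A Σ + Σ Aᵀ + S_C = 0`.

A transition is a controlled diffusion `dx = A x dt + v dt + C dw`
constrained to start in `N(μ₀, Σ₀)` and end in `N(μ_T, Σ_T)` at horizon
`T`.  The cost of a controlled law `P̃` relative to the uncontrolled law
`P` is the path KL divergence; by Girsanov's theorem
`2 D_KL(P̃‖P) = E ∫₀ᵀ ‖v‖²_{S_C⁻¹} dt`, so minimizing either is the same
problem (a Gaussian Schrödinger bridge).  We report `J* = 2 D_KL` — the
expected weighted quadratic input — and expose the KL value alongside it
(`BridgeSolution.kl`) so no consumer has to guess the factor of two.

### Optimal solution

The minimizer is a linear feedback diffusion

    v*(x, t) = −S_C (Π(t) x − m(t)),

where the feedback potential solves the Riccati equation
`Π̇ = −AᵀΠ − ΠA + Π S_C Π`, an auxiliary potential solves the
opposite-sign equation `Ḣ = −AᵀH − HA − H S_C H`, and the controlled
covariance is `Σ(t) = (Π(t) + H(t))⁻¹` with boundary coupling
`Π + H = Σ⁻¹` at both ends.  Both Riccati flows linearize in the inverses:
with `Φ(t) = e^{At}` and the Gramian `M(s,t) = ∫ₛᵗ Φ(t,τ) S_C Φ(t,τ)ᵀ dτ`,

    Π(t)⁻¹ = Φ(t) Π(0)⁻¹ Φ(t)ᵀ − M(0,t),
    H(t)⁻¹ = Φ(t) H(0)⁻¹ Φ(t)ᵀ + M(0,t).

The cost decomposes exactly into a mean part and a covariance part
(`total_cost` returns both):

    J_mean = μ_dᵀ M(T)⁻¹ μ_d,            μ_d = μ_T − Φ(T) μ₀,
    J_cov  = ∫₀ᵀ tr(S_C Π) dt − [tr(Π(T)Σ_T) − tr(Π(0)Σ₀)]
           = ∫₀ᵀ tr(Π S_C Π Σ) dt        (integration by parts).

`J_mean` depends only on the marginal means and equals the deterministic
minimum-energy cost with input matrix `B = C`; `J_cov` depends only on the
marginal covariances.  Both forms of `J_cov` are computed and must agree to
1e-6 relative, else the solver raises an internal-consistency error.

The optimal mean path and feedforward term are

    μ(t) = Φ(t) μ₀ + M(0,t) Φ(T,t)ᵀ M(T)⁻¹ μ_d,
    m(t) = Π(t) μ(t) + Φ(T,t)ᵀ M(T)⁻¹ μ_d,

so the mean obeys the classical minimum-energy trajectory regardless of the
covariance program.  Per-ROI inputs are

    I_mean(k) = (S_C ∫ (Πμ−m)(Πμ−m)ᵀ dt S_C)_kk,
    I_cov(k)  = (S_C ∫ Π Σ Π dt S_C)_kk,     I(k) = I_mean(k) + I_cov(k),

the expected squared control delivered at node k; when `S_C = I` they sum
to `J*` exactly.

### Solving the boundary-coupled system

Rather than iterating on `Π(0)`, the solver computes `Π(T)` in closed form
by reduction to static Gaussian entropic optimal transport.  Whitening the
prior transition kernel `N(Φ(T)x₀, M(T))` (variables `u₀ = G x₀`,
`u_T = G Φ⁻¹ x_T`, `G = (Φ⁻¹ M Φ⁻ᵀ)^{−1/2}`) makes the kernel `N(u₀, I)`;
writing `R = Σ̂₀^{1/2}` for the whitened initial covariance, the optimal
coupling solves the quadratic matrix equation `W² + W = R Σ̂_T R`, i.e.

    W = ( (I + 4 R Σ̂_T R)^{1/2} − I ) / 2,

the whitened conditional covariance is `V = R⁻¹ W R⁻¹`, and
`Π(T) = Φ⁻ᵀ G (V⁻¹ − I) G Φ⁻¹`.  `Π(t)` is then propagated backwards along
its exact linear-fractional flow

    Π(t) = Φ(T,t)ᵀ (I + Π(T) M(t,T))⁻¹ Π(T) Φ(T,t),

which stays valid when `Π(T)` is singular (the zero-cost case), and
`H(t)` forwards through the analogous resolvent form from
`H(0) = Σ₀⁻¹ − Π(0)`.  Two implementation facts matter:

- `H` need not be positive definite — only `Π + H = Σ⁻¹` must be.  The
  resolvent propagation never inverts `H(0)`, and `Π + H ≻ 0` is verified
  at every grid point.
- Boundary residuals `‖Π(0)+H(0)−Σ₀⁻¹‖/‖Σ₀⁻¹‖` (and at `T`) are checked
  after the solve; in practice they sit at machine precision (≈1e-13).  If
  they ever exceed 1e-8 a Newton polish on `Π(T)` runs, and failure to
  converge raises rather than returning a bad solution.

A target equal to the uncontrolled endpoint (relative Frobenius distance
< 1e-10) short-circuits to `Π ≡ 0`.

## Estimation pipeline

Given per-subject ROI series sampled at interval `dt`:

1. **Trace normalization.**  Each subject's series is divided by the square
   root of the trace of its reference-segment covariance (the resting run,
   or the task-free moments of a task run), making the reference covariance
   trace 1 and the series concatenable across subjects whose raw units are
   arbitrary.  All downstream cost ratios are invariant to per-subject
   rescaling by construction.
2. **Sparse VAR(1).**  `x(t+dt) = a x(t) + b + ε` fitted row-wise by lasso
   (scikit-learn convention: penalty λ multiplies `‖w‖₁` against
   `1/(2N)‖y−Xw‖²`; λ = 0 is OLS via least squares).  Regression pairs
   never span a concatenation boundary.  λ defaults to 5-fold
   cross-validation of one-step-ahead error over an 8-point logarithmic
   grid anchored at the data-driven `λ_max = ‖Xᵀy‖_∞/N`; a fixed λ can be
   configured.
3. **Continuous-time conversion.**  `A = log(a)/dt` (principal matrix
   logarithm; eigenvalues of `a` must lie inside the unit disk and off the
   closed negative real axis, otherwise the error message advises a smaller
   sampling interval).  The noise rate inverts the exact discrete moment
   identity: using `log(a⊗a) = L⊗I + I⊗L`, the n²-dimensional Kronecker
   system reduces to one discrete Lyapunov solve,
   `S_C = −W/dt` with `W − a W aᵀ = L S_ε + S_ε Lᵀ`, `L = log a`.
   For exact inputs the round trip through the exact discretization is
   exact (the 1-D case returns `c²` to 1e-10).  Finite-sample estimates can
   leave the PD cone; eigenvalues below `1e-6·λ_max` are floored with a
   warning.
4. **States.**  Rest: empirical mean and covariance of the pooled rest
   series.  Task: mean of task-performing moments minus mean of task-free
   moments; covariance of the task-performing moments.  Before use as
   bridge marginals, covariances are shrunk convexly toward their diagonal
   just enough to bound the condition number by 1e8 (bisection on the
   shrinkage weight).
5. **Bootstrap.**  Each replicate draws k subjects without replacement,
   re-runs steps 1–4, solves the bridge from rest to each task state, and
   records `(J_mean, J_cov, J_total, J_cov/J_mean)` plus input maps.  The
   ratio is computed within each replicate and then averaged.  Failed
   replicates are recorded; more than 10% failures aborts.

An optional switch (`match_rest_cov`, off by default) replaces the fitted
`S_C` by the one making the implied steady state equal the empirical rest
covariance exactly (`S_C = −(AΣ_rest + Σ_rest Aᵀ)`, PD-projected if
needed).  Default off because the residual-implied noise rate is the
maximum-likelihood choice and the stationarity-matched one can be
incompatible with the fitted drift.

`dt` is a required input everywhere (config default 0.72 time units, an
HCP-like repetition time); no sampling interval is ever assumed silently.

## Synthetic data: what it emulates, what it does not

The cohort generator produces, per subject, a resting run (stationary OU)
and task runs alternating task-free blocks (raw OU) with task-performing
blocks whose samples are affinely mapped to `δ + L x`, giving them exactly
mean `δ` and covariance `L Σ₀ Lᵀ`; each subject's whole recording is
multiplied by a subject-specific scale factor.  Defaults used by the tests
and the acceptance script: 20 subjects, 6 ROIs, 600 rest and 600 task
timepoints at `dt = 0.72`, blocks of 30 timepoints, subject scales spread
over [0.5, 2], a focal mean effect (`δ = 0.5` on one ROI, `L = I`) or a
spread covariance effect (`δ = 0`, `L` a full rotation with per-ROI
variance scalings in [0.75, 1.25]).  The ground-truth drift spectrum is
mapped into `Re λ ∈ [−1.3, −0.3]` per time unit: faster modes are
unidentifiable at the sampling interval, slower ones never decorrelate
within a block, and neither regime is characteristic of parcellated BOLD;
the noise rate is scaled so the stationary covariance has trace `n`
(variance-normalized signals).

Task blocks are affine transformations of stationary OU samples, not a
second controlled SDE: the estimation pipeline consumes only block moments,
and this choice makes the ground truth exact.  Consequences: block
transitions are instantaneous (no hemodynamic ramp), there is no
within-block nonstationarity, no measurement noise distinct from the
process noise, and no violation of linearity.  Passing tests therefore
demonstrate correctness of the estimator and the cost machinery under the
model's own assumptions — not robustness to the preprocessing artifacts,
nonlinearity, or hemodynamics of real fMRI.

The controlled-path simulator integrates the optimal SDE by Euler–Maruyama
with `Π` and `m` linearly interpolated between grid points (step guard
`euler_dt ≤ T/500`) and records per-path endpoints, weighted quadratic
cost, and per-node costs.  It shares no code with the analytical cost path
and serves as the solver's independent oracle: totals, endpoint moments,
and node inputs must agree within 3 Monte-Carlo standard errors.

## Numerical choices

- **Time integrals** (`M(s,t)`, exact discretization noise): Van Loan block
  exponential `exp(t[[A, S_C],[0, −Aᵀ]])`, computed on a base step with
  `‖A‖t ≤ 2` and composed by doubling (`M(2t) = Φ M Φᵀ + M`) — the raw
  block form overflows for long horizons because `−Aᵀ` is anti-stable.
- **Grid**: uniform, default 200 intervals on `[0, T]` (minimum 50);
  costs by composite Simpson.  `total_cost(refine=True)` doubles the grid
  until `J_cov` moves by < 1e-6 relative (≤ 3 doublings).
- **Default horizon** `T = 1.0` time units.
- **Stability tolerance**: steady-state computations require
  `Re λ(A) < −1e-10`; operations that do not need stability accept any `A`.
- **Symmetrization**: symmetric outputs are returned as `(X+Xᵀ)/2`;
  asymmetry beyond 1e-8 relative triggers a warning.
- **PD checks**: marginals must have `λ_min > 1e-10 λ_max`; `S_C` must have
  `λ_min > 1e-12 λ_max`; `Π + H` must be PD at every grid point.
- **Matrix square roots** via symmetric eigendecomposition (never `sqrtm`
  on nonsymmetric inputs); matrix logarithm is the principal branch with
  imaginary residual tolerance 1e-8 (hard failure above 1e-6, with advice
  to reduce `dt`, rather than silently truncating).
- **Ties** in map rankings (top-k, coverage) break by descending value then
  ascending ROI index.

## Known limitations

- Linear dynamics with additive Gaussian noise; nonsingular `S_C`
  (degenerate or rank-deficient noise is out of scope), input coupled
  through the identity (general input matrices `B ≠ I` are not supported).
- Time-invariant `A`, `C` over the horizon.
- Estimation assumes regularly sampled, stationary resting segments; the
  matrix logarithm requires the sampling to resolve the fastest dynamics.
- The entropy/coverage/top-k analytics operate on input maps already
  computed; they make no inferential claim across subjects beyond the
  bootstrap spread.
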