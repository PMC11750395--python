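# Methods

## Model

Development of a seed is tracked on an abstract physiological axis *x*:
imbibition starts at *x* = 0, seedling emergence occurs at *x* = *L*₀ and
tillering completes at *x* = *L*₁.  Both stages are taken as one
physiological unit each (*L*₀ = 1, *L*₁ = 2), which makes the speed *u* the
fraction of a stage traversed per day.  Within a stage the seed-density
*n*(*x*, *t*) follows the drift–diffusion equation ∂n/∂t = D ∂²n/∂x² −
u ∂n/∂x.  The microscopic picture is a jump process with strictly positive
physiological advancements per time step; truncating its master equation at
second order (drift = first moment rate, diffusion = half the second moment
rate) yields the PDE.  Two consequences of that truncation matter for
testing and are verified explicitly by the random-walk micro-simulator:

* the truncation is accurate only in the advection-dominated regime
  Pe = *u L*₀/*D* ≫ 1.  For Gamma-distributed positive increments the
  walker position at time *t* is exactly Gamma(*u*²*t*/2*D*, 2*D*/*u*)
  regardless of the micro step (Gamma is closed under convolution), so the
  gap to the Gaussian PDE solution is governed by the walk's skewness
  2/√(*u L*₀/2*D*) — a property of Pe, not of the micro step.  The test
  suite therefore checks agreement (KS ≤ 0.02 at 10⁵ walkers) at Pe = 200,
  inside the regime where the model claims validity, and separately checks
  that the sampled law is insensitive to the micro step;
* no positive-support step distribution with these two moments converges to
  the Gaussian limit as the micro step shrinks (the skewness of the sum is
  step-independent), so "refine the micro step" is not a convergence knob.
  Field-realistic Péclet numbers (20–1000 here) keep the truncation error
  at or below the counting noise of real trials.

## Closed-form germination solutions

With the seed pulse released at the inlet and zero inflow afterwards, the
semi-infinite-domain density is the classical impulse flux-injection
profile (in α = D/(uL₀), τ = ut/L₀, X = x/L₀):

n = (N₀/L₀) [ (πατ)^(−1/2) e^(−(X−τ)²/(4ατ)) − (2α)^(−1) e^(X/α) erfc((X+τ)/√(4ατ)) ]

`analytic.density` returns the single free Gaussian
(4πατ)^(−1/2)-normalised leading term by default and the full profile with
`with_correction=True`; the two differ only near the inlet and their gap
shrinks like √α.  The erfc product is evaluated through `erfcx` to avoid
overflow.  The profile was validated against the finite-volume solver
(second-order convergence in dx; ≤ 0.3% of N₀ on a 400-cell grid at
Pe = 100 with a reduced time step).

The cumulative emergence curve `analytic.emerged_fraction` is
E = ½ erfc((1−τ)/√(4ατ)) by default — exact for the monotone physiological
walk in the Gaussian limit, with E(τ=1) = ½ — plus, with
`with_correction=True`, the boundary term ½ e^(1/α) erfc((1+τ)/√(4ατ))
that accounts for back-dispersion across the emergence boundary.  The
corrected form tracks the finite-volume outflux to ≤ 0.01 absolute for
Pe ∈ {20, 100, 1000} and is what the calibration factories use; the two
forms agree as Pe → ∞.  Quantiles invert the curve by bracketed root
finding (tolerance 10⁻⁸ days).

## Finite-volume solver

Explicit forward-Euler in time, cell-centred second-order fluxes: interior
faces carry D(m_{i−1} − m_i)/δx + u(m_{i−1} + m_i)/2, the inlet face
carries zero, the stage-end faces carry the purely advective u·m (the
zero-gradient outflow condition), and the junction face into the first
tillering cell carries γ·u_G·n(L₀).  The initial pulse is the whole seed
lot in the first cell.  Cumulative emergence and completed tillers are
accumulated from the boundary fluxes each step, which makes both
conservation laws telescoping identities: seeds in transit + emerged = N₀,
and tillers in transit + completed = γ × emerged, each holding to round-off
(asserted at 10⁻⁸ relative in the tests).

Three step constraints are enforced as hard errors: the advective CFL
δx > u·δt, the cell-Péclet bound u·δx/D < 2 (what keeps the central
advective flux non-oscillatory — hence error, not warning), and the
explicit-diffusion bound D·δt/δx² ≤ 0.4.  Automatic step selection applies
a safety factor 0.5 and additionally caps δt at 0.2·D/u², because
forward-Euler advection contributes an anti-diffusion −u²δt/2 that would
otherwise distort the effective dispersion at high Péclet (this cap keeps
it below 10% of D).  Time-varying drivers are evaluated at the beginning of
each step as a step function; a constant series reproduces the constant-
parameter run exactly.

The default field observable for tillering is the cumulative outflux at
*L*₁ (completed tillers).  Field counts might instead see every initiated
tiller; the trajectory also exposes `tillers_visible` (in-transit +
completed) for that convention.

## Calibration

Grid search over (u, D) maximising R² (1 − SS_res/SS_tot about the
observation mean), exactly at the observation days, replicates pooled by
concatenation.  Defaults: 30 log-spaced speeds in [0.02, 0.5] day⁻¹ and 30
log-spaced dispersions in [10⁻⁴, 5·10⁻²] (the procedure itself prescribes
no grids); ties break deterministically toward smaller u, then smaller D;
failing grid points are skipped with a warning.  Nested-grid local
refinement (9×9 windows shrinking 4× per pass) resolves the optimum to
10⁻⁴ in both parameters.

The germination-stage factory evaluates the corrected closed-form curve —
the germination stage admits the closed form, and the default grids reach
Péclet numbers (up to 5·10³) where a central-flux grid would need δx
< 4·10⁻⁴ — while the finite-volume solver remains the oracle it is verified
against and the engine for coupled/time-varying runs.  The tillering
factory uses the cascade structure of the linear two-stage system: the
completed-tiller curve is the convolution of the emergence flux with the
tillering-stage crossing law (Δ = 0.05 day internal grid), verified against
the coupled finite-volume run to < 1% of γN₀.

Viable seeds cannot be counted in the field, so per-treatment viable
fractions are the final emerged counts normalised by the best treatment
(cross-treatment-maximum convention; the per-treatment alternative is a
matter of setting `viable_frac` directly).  γ is estimated per treatment as
final tillers / emerged seedlings (a global-γ option averages across
treatments).  Sequential fitting: germination first, then tillering with
(u_G, D_G) frozen.

## Environmental response

u_G = [a(T−T₀) − b(T−T₀)²]·Θ^β(Θ−Θ_r)(Θ₀−Θ)^β with defaults a = 1.42
day⁻¹ °C⁻¹, T₀ = 12.6 °C, b = 0.23 day⁻¹ °C⁻², β = 1.2, Θ₀ = 1.0,
Θ_r = 0.05 (Θ as a fraction of field capacity throughout).  The quadratic
is clamped at zero below T₀ and on the supra-optimal branch (above
T₀ + a/b ≈ 18.8 °C with the defaults), and the moisture factor is clamped
outside (Θ_r, Θ₀); the maximising temperature T₀ + a/(2b) is checked
against the closed form in the tests.

Fitting: nonlinear least squares.  On a factorial design with a handful of
moisture levels the six-parameter problem is rank-deficient — u = g(T)·f(Θ)
is invariant under g → c·g when (a, β, Θ₀, Θ_r) re-solve f exactly, and
three moisture levels cannot pin three moisture-shape parameters plus the
shared scale.  The default fit therefore holds Θ₀ and Θ_r fixed (they are
critical water contents with physical interpretations, not free shape
parameters) and fits (a, T₀, b, β), which is an exact round-trip on
noise-free factorial data; `free_all=True` exposes the full six-parameter
fit for richer designs.

The dispersion–speed relation is a two-parameter power law D = c·uᵈ fitted
in log space (simplest monotone positive family; a linear form is
provided), and driver time-averaging runs from sowing to either a fixed day
count (prediction mode, default 30 days) or the day of 90% of final
observed emergence.

## Hydrotime comparison model

G(t, ψ) = F_ψb(ψ − θ_H/t) with a three-parameter Weibull (shape, scale,
location) base-water-potential distribution, temperature held fixed.
Fitting is joint nonlinear least squares across ≥ 3 water-potential levels
from a documented five-point multi-start list (deterministic); the
Monte-Carlo oracle (10⁶ Weibull draws) agrees with the closed form to
≤ 10⁻³.  This module exists to score the two model families on the same
curves by R²; the location parameter is unbounded below and only
constrained above by the largest observed ψ.

## Synthetic data

The generator emulates an October-sown winter-wheat drilling trial: three
sowing dates (temperature gradient), three moisture regimes (75/65/55% of
field capacity, held by top-up irrigation), three replicate plots, daily
emergence counts of ~100 seeds on a 1 m row section and weekly tiller
counts.  Drivers are hourly: a cooling autumn trend (17 °C at sowing,
−0.10 °C/day), a 4 °C diurnal sinusoid peaking mid-afternoon, and AR(1)
noise; soil water follows irrigation sawtooth cycles of ±0.05 around the
target (capped at 0.85).  Per treatment, the time-averaged drivers map to
u_G through the environmental response, D_G through the power-law
dispersion relation, u_T = 0.35·u_G (tillering runs over months rather
than weeks) and γ = 4 tillers per seedling — typical for autumn-sown wheat
at this density.

Observation noise is binomial with monotone coupling: each seed carries one
uniform draw and is counted from the first day the model emergence
probability passes it, so cumulative counts never decrease, matching field
counting of cumulative emergence.  Occasional count decreases seen in real
trials (bird predation) are off by default (`allow_decreases`).  Tiller
counts are Poisson around the model curve.  What passing tests on this
surface do **not** show: robustness to systematic counting bias, seed
dormancy, spatially correlated soil heterogeneity, or driver measurement
error — the generator draws from the model family itself, so recovery tests
establish identifiability and implementation correctness, not model
adequacy for any particular field.

## Problem sizes and determinism

The standard verification runs: 15 temperature × moisture combinations on a
200-cell grid for the environmental-response round trip (~10 s), 20 seeded
binomial replicates for the noise study (~2 s), 10⁵ walkers at Pe = 200 for
the random-walk check (~40 s), and 10⁶ draws for the hydrotime oracle.
Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); identical seeds reproduce identical outputs,
and all pipeline entry points log their parameters and seeds.

## Known limitations

* The analytic path treats the emergence boundary as transparent
  (semi-infinite domain); finite-domain effects are the solver's job, and
  at Pe < ~10 neither closed form is trustworthy.
* No flux limiter: the solver refuses (rather than stabilises) cell-Péclet
  violations, by design.
* Tillering is phenomenological — nutrients and genotype enter only through
  (u_T, D_T, γ).
* The hydrotime module deliberately omits thermal-time and oxygen-time
  axes; it exists for same-data comparison at fixed temperature.
* γ estimation from final counts inherits any censoring of the tiller time
  series; if counting stops before the tillering wave completes, γ is
  biased low.
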