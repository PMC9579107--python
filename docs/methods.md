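# Methods

## Model

Three coupled number densities on a line: right-movers ρ₊, settled cells ρ₀,
left-movers ρ₋. Kinetics (matrix ℳ, species order (ρ₊, ρ₀, ρ₋)): movers
settle at λs, tumble (reverse) at λe and die at μ; a settled cell is
replaced, at rate λd, by one right- and one left-moving daughter. Column
sums of ℳ are (−μ, +λd, −μ): total cell number changes only through mover
death and settled-cell doubling, and the weighted density
R = ρ₊ + ρ₋ + 2ρ₀ is exactly conserved on the line λs = μ. Transport:
drift ±v± and diffusion D for movers only. Interactions enter as a
density-dependent flux ∂x[(∂x𝒰)ρ] with 𝒰 = diag(−κρ₀, κ₀ρ₀, −κρ₀):
movers drift up gradients of the settled density (strength κ ≥ 0), settled
cells repel each other (κ₀ ≥ 0, a nonlinear self-diffusion). Growth is
either linear (ℳρ) or saturating: ℳ_Dρ + ℳ_OD R(ρ) with the componentwise
logistic source R(ρ)α = ρα(1 − ρα/ρα,c); only the off-diagonal (growth)
part saturates, so the logistic fixed point is not the carrying capacity
itself.

Units: time in 1/λe, length in domain lengths L, density dimensionless.
κ and κ₀ are quoted in 1/λe; this implicitly fixes a reference density
scale, which we take to be the dimensionless unit (an assumption — the
interaction terms only ever enter through the products κρ and κ₀ρ).
Presets carry the *Caulobacter crescentus* SI values with converters; the
physical domain length adopted there is 1 mm.

## Well-mixed kinetics

Closed-form eigenvalues E₁ = −(μ + 2λe + λs),
E₂,₃ = −(μ + λd + λs ± Λ)/2 with
Λ = sqrt((μ + λd + λs)² + 4λd(λs − μ)). E₁, E₂ are always stable; sign(E₃)
= sign(λs − μ). A negative radicand (not reached in the regimes studied)
returns complex values with a warning. Time evolution uses scipy's
scaling-and-squaring matrix exponential — deterministic, and robust at the
defective point Λ = 0 where an eigendecomposition would fail. The logistic
variant integrates with classical RK4, default dt = 10⁻⁴/λe.

## Displacement moments and ISF

For free cells (κ = κ₀ = 0) the model is diagonal in wavenumber:
ρ̃(k,t) = exp[(−k²𝒟 − ik𝒱 + ℳ)t] ρ̃(k,0). Moments are k-derivatives of the
ISF at k = 0. Rather than finite-differencing in k, the vectors
yₘ = ∂ₘρ̃/∂kᵐ|₀ satisfy the closed block-triangular system
dyₘ/dt = ℳyₘ − imV yₘ₋₁ − m(m−1)𝒟 yₘ₋₂ (the generator is quadratic in k),
solved exactly with one 3(n+1)-dimensional matrix exponential — no step-size
artifacts. A central finite-difference route with Richardson extrapolation
is kept as a cross-check. Normalizations N(t), Nα(t) always come from the
k = 0 components of the same solve, never from quadrature. The default
initial condition is a settled delta at the origin, ρ̃(k,0) = (0,1,0); the
ISF convention F(k,t) = P̃(k,t)P̃(−k,0)N(t) then reduces to F(0,t) = N(t),
which fixes the normalization for growing populations.

The long-time diffusive→ballistic MSD crossover t_l2 has no compact closed
form; it is defined operationally as the intersection of a least-squares
linear (diffusive) asymptote — fitted on log-spaced samples where the local
log-log slope is within 0.2 of 1 — with the ballistic asymptote
(slope·t)², the slope being the closed-form long-time MD coefficient.

The particle oracle simulates the identical process cell-by-cell
(exponential clocks, exact Gaussian drift-diffusion increments between
events, doubling as branching), starting from one settled cell per
ancestor. Density-weighted moments are ratio estimators
Σcells xⁿ / Σcells 1 across ancestors with delta-method standard errors;
spectral and particle routes agree within 3 SE in the tests.

## Linear stability and the separatrix

Linearizing about the symmetric homogeneous stationary state
(ρ̂₊ = ρ̂₋, ρ̂₀ = 2μ/λd ρ̂₊) gives a 3×3 Jacobian J(k); its eigenvalues are
computed numerically per k (more robust than the closed-form cubic) and
tracked across k by minimal-distance assignment. The leading branch obeys
s₁(0) = E₃ and, for κ₀ = 0, s₁(∞) = 2κρ̂₊λs/D − λd, yielding the two
endpoint stability conditions; κ₀ > 0 caps the unstable band
(s ~ −κ₀ρ̂₀k²; note that as a statement about the *largest* eigenvalue
this asymptote holds when κ₀ρ̂₀ < D, otherwise the free mover branch
−Dk² decays more slowly). The largest unstable wavenumber k_r is bracketed
on a 2000-point linear grid and refined by Brent's method; a finite
periodic domain supports the instability when k_r > k₀ = 2π/L.

The separatrix k_r = k₀ is located by bisecting v_m at fixed v_r
(tolerance 10⁻⁴; (v_r, v_m) → (v₊, v₋) keeping D fixed) and fitted by
least squares with a quadratic, reporting parameter standard errors.

**Normalization choice.** The linear problem depends on the homogeneous
state only via κρ̂ and κ₀ρ̂. The package default for separatrix work is the
stationary state with unit conserved density, R₀ = 1 — at the
pattern-formation rates this is ρ̂ = (1/6, 1/3, 1/6). This choice is
physically natural (one unit of conserved population per domain) and makes
the theoretical and numerical separatrices mutually consistent, since the
PDE scans are initialized from the same R₀ = 1 stationary state. The
attraction-only dispersion checks instead use ρ̂₊ = 1, the value at which
the documented marginal case (D = 2v₊²/λe with κ = 1/λe and unit rates)
is exactly marginal.

## PDE solver

Second-order central differences for diffusion and advection; the
interaction flux is discretized conservatively, F_{i+1/2} − F_{i−1/2} with
the drift (∂x𝒰) and density averaged at faces, so transport and
interaction tendencies integrate to zero to machine precision. Central
(rather than upwind) advection is appropriate at the default grid Péclet
numbers; time stepping is classical RK4, default dt = 10⁻⁴/λe, n_x = 128–256
on L = 1. A conservative explicit-stability bound (effective diffusivity
D + κ₀max ρ₀ + κ max ρ±, RK4 real-axis constant 2.78) is enforced at
start-up; NaN or densities below −10⁻⁹ abort with the last good snapshot.
Initial conditions: uniform stationary state (linear: exact; logistic:
Newton fixed point) plus seeded i.i.d. Gaussian noise, a narrow settled-cell
Gaussian peak, or a single seeded Fourier mode (optionally along a chosen
dispersion eigenvector, which excites one branch cleanly). Early exit on
translation-invariant shape convergence (change of the Fourier modulus of
the total density below tolerance per 10³ steps) or on conclusive amplitude
bounds.

## Pattern classification and the state diagram

A long-time solution is classified from the relative peak-to-peak
modulation A = (max − min)/mean of the total density: A ≥ 10⁻² is a wave,
whose measured speed (periodic cross-correlation of late snapshot pairs
with parabolic sub-grid interpolation, averaged, divided by √(Dλe))
separates static (|v_s| < 10⁻²) from traveling. Both thresholds are
configuration keys; neither is sharply determined by the physics, they
separate the noise floor from developed patterns at the default noise
amplitude.

Finite-horizon runs need care: near the transition the only unstable
domain mode grows at a rate that vanishes linearly in the distance to the
separatrix (≈ 0.02/λe one bisection cell inside it), so no fixed-length
run can push its amplitude over a fixed threshold arbitrarily close to
onset. Scans therefore classify saturated or converged runs by amplitude,
and unconverged sub-threshold runs by the sign of the fitted exponential
growth rate of the pattern amplitude over the late half of the run — a
deterministic, seed-robust criterion that measures the same instability
the state diagram quantifies. The scan bisects v_m ∈ [1, 6] (wave below,
uniform above: faster running smears the attraction-driven accumulation
out) to depth 5–6 at each v_r and fits the transition quadratically.

Problem sizes: the shipped scan uses n_x = 128, dt = 10⁻⁴/λe and at most
2·10⁵ steps per run at 5 v_r values — about 35 PDE runs and well under two
minutes on one CPU with the numba kernels; deeper bisection, longer runs
and finer v_r grids are plain configuration changes.

## Synthetic data

The package generates all of its own inputs. The noisy-uniform generator
emulates small density fluctuations around the stationary state
(i.i.d. Gaussian per grid point and field, amplitude 10⁻³, seeded); real
experiments would have correlated, demographically structured fluctuations,
so passing tests demonstrate correctness of the deterministic field model,
not realism of the noise. The `translated_wave` fixture is a labelled
synthetic trajectory (a band-limited random profile rigidly translated by
exact spectral shifts) used solely to validate the wave-speed estimator
against a known ground truth.

## Limitations

* One spatial dimension, scalar order; no nematic alignment, no
  run-reverse-flick kinematics, no 2-D/3-D generalization.
* Linear-growth analyses assume the separating line λs = μ for stationary
  states; off that line only the logistic variant has finite steady states.
* The spectral moment machinery covers free cells only (interactions make
  the model nonlinear and are handled by the PDE solver).
* Closed-form short-time expansions are specific to the settled-delta
  initial condition (an initially mobile cell gives merely linear
  short-time laws and identical long-time asymptotes).
* No stochastic PDE: noise enters only through initial conditions.
* The explicit solver requires the stated stability bound; strongly
  peaked logistic states at coarse grids may demand smaller dt.
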