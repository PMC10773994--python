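# Methods

## Model

A planar root of radius r is described by the tangent angle θ(s, t) of its
centerline, with arc length s from the clamped base (θ(0, t) = θ₀) to the
tip at s = L(t), and curvature κ = ∂θ/∂s. Gravisensing is apical: the
statocyte-bearing root cap reports the tip inclination θ_tip relative to the
stimulus direction θ_g = π/2, and the whole subapical growth zone (fixed
length L_gz) responds to that single signal. Proprioception opposes local
curvature. Inside the growth zone, with uniform elemental growth rate
ε̇₀ = v_g / L_gz,

    (r / ε̇₀) Dκ/Dt = −β sin(θ_tip − θ_g) − γ r κ,

where D/Dt = ∂/∂t + v ∂/∂s follows the tissue (v(s,t) is the cumulative
growth velocity) and β, γ are the dimensionless gravitropic and
proprioceptive sensitivities. Material exiting the growth zone freezes its
curvature; the organ lengthens linearly, L(t) = L₀ + L_gz ε̇₀ t. Elastic
deformation and external forces are neglected (thin organs growing against
a low-resistance substrate); so are 3-D effects and torsion.

Because the apical signal is shared along the growth zone, an initially
straight organ keeps a spatially uniform growth-zone curvature κ_gz(t), and
the tip angle decomposes into the frozen (mature-zone) angle plus the
growth-zone traced angle. In nondimensional variables k = L_gz κ_gz and
τ = ε̇₀ t this closes into

    K′ = k,  k′ = −η sin(K + k + θ̃₀) − γ k,  K(0) = k(0) = 0,

with η = β L_gz / r (β rescaled by the growth-zone slenderness) and
θ̃₀ = θ₀ − θ_g; θ_tip(τ) = θ₀ + K(τ) + k(τ). We integrate this augmented
first-order system rather than the equivalent second-order arcsin form

    −(k″ + γ k′) / √(η² − (k′ + γ k)²) = k + k′,

because the arcsin form is a 0/0 limit at τ = 0 for horizontal
gravistimulation (k′(0) + γk(0) = η there); the arcsin form is kept as a
residual cross-check (`residual_arcsin_form`), evaluated with
finite-difference derivatives and masked where the denominator degenerates.

### Small-angle limit and regimes

Linearizing the sine gives k″ + (η + γ)k′ + ηk = 0 — a damped harmonic
oscillator with ω₀ = √η, Γ = η + γ, Q = ω₀/Γ and critical proprioception
γ_crit = 2√η − η. The ηk term originates in the frozen-curvature integral:
a growing organ carrying fixed curvature keeps changing its tip angle
(*passive orientation drift*), which destabilizes the turn; proprioception
enters only the damping.

One subtlety matters for classifying simulations. Under the tilt-from-rest
initial condition the deviation φ = θ_tip − θ_g starts at θ̃₀ with
φ′(0) = −η θ̃₀, and for η > 1 the slow decay mode carries a coefficient of
the opposite sign: even critically damped and overdamped solutions with
γ_crit ≤ γ < 1 cross the stimulus direction *once* and then converge
monotonically from the far side (at γ = 1 the deviation decouples,
φ′ = −η sin φ, and the crossing disappears). The underdamped regime
γ < γ_crit is therefore detected as a *returning* overshoot — at least two
stimulus crossings (`overshoots_gravity`); `gravity_crossings` reports the
raw count. Crossings near critical damping have amplitudes many orders
below the angles themselves, so the classifier integrates the equivalent
(φ, k) system — φ as a state variable, effectively pure relative error
control — instead of reconstructing φ = θ̃₀ + K + k, which would cancel
catastrophically.

## Numerics

- Reduced ODEs: adaptive explicit Runge–Kutta (rtol 1e-8, atol 1e-10),
  dense output for interpolation onto arbitrary sampling grids.
- Material-point oracle (`lagrangian_oracle`): positions and curvatures of
  discrete material points advected with v(s, t); the mature zone freezes
  automatically because the local growth rate (and with it the whole
  right-hand side) vanishes there. Fixed-step Heun updates with
  Δτ ≤ min(0.5/(η + γ + 1), 2·10⁻³); midpoints are inserted where gaps
  between points exceed 1.5× the initial spacing (material near the tip
  stretches apart exponentially). Supports uniform, triangular and custom
  growth-rate profiles and local as well as apical sensing. At 400 material
  points the tip trajectory agrees with the reduced model to ~1e-5 rad.
- Curvature from angles: central differences on the interior, second-order
  one-sided at the endpoints, on possibly non-uniform grids.
- Shape reconstruction: growth zone carries k(τ)/L_gz; a mature-zone point
  at arc length s froze when the zone base passed it, at τ′ = (s − (L₀ −
  L_gz))/L_gz; any pre-existing mature zone (L₀ > L_gz) is straight. The
  field is continuous but not smooth at the zone boundary. Centerlines come
  from cumulative trapezoidal integration of (cos θ, sin θ).

## Comparison models

- **No-growth model** (`solve_ac_model`): fixed length, uniform curvature,
  apical sensing; k′ = −η sin(k + θ̃₀) − γk. Without the frozen-curvature
  memory there is no drift term: the tip aligns with the stimulus only for
  γ = 0 and otherwise stalls at η sin(k* + θ̃₀) = −γ k* (for η = γ = 1 and
  horizontal tilt, cos k* = k*, k* ≈ 0.739085).
- **Whole-organ exponential growth** (`solve_ace_exponential`): the
  coleoptile-like early phase, L(τ) = L₀ eᵗ. With *apical* sensing the
  curvature stays uniform and the model collapses to a scalar first-order
  flow that relaxes onto a quasi-static equilibrium pinned to the stimulus
  — it cannot sustain oscillations, with either the initial-length or the
  instantaneous-length definition of η (both exposed). The oscillatory
  whole-organ phenomenology (tip crossing the stimulus for every γ,
  sustained swinging at moderate γ) requires *distributed* sensing, so the
  default solves the local-sensing field equation as a stiff
  method-of-lines system on the material coordinate. Even then, strong
  proprioception (γ ≈ 5) damps the tip oscillation below 1e-4 rad by
  τ = 10; the often-quoted "never settles" behaviour is a small-to-moderate
  γ phenomenon.

## Inference

`TipAngleFitter` fits observed θ_tip(t) to the reduced model by bounded
nonlinear least squares over {γ, η, θ₀} (trust-region reflective), mapping
time through a per-root ε̇₀ = v_g/L_gz (cohort-mean fallback with a logged
warning when no geometry is supplied). Bounds γ ∈ [0, 20], η ∈ (0, 20],
θ₀ ∈ (0, π/2]: θ₀ is bounded positive because for θ_g = π/2 the initial
conditions are invariant under θ₀ → −θ₀, so only the positive branch is
identifiable. The loss has local minima, so the fit restarts from a
deterministic 4×2 log-grid over (η, γ) with θ₀ = 0.01 and keeps the best
sum of squares; fitting is fully deterministic given the data. Covariances
come from the Jacobian at the optimum; constant (degenerate) trajectories
are flagged rather than raised. The restricted γ = 0 fit
(`fit_without_proprioception`) is the nested model used to show that
proprioception is required.

The independent maximal-bending estimator is
β_bend = max_t d(θ_tip − θ_gz0)/dt · r / v_g. Since θ_tip − θ_gz0 = k and
k′(0) = η for horizontal tilt, β_bend equals β exactly in the continuum;
the derivative is a Savitzky–Golay quadratic slope over 5 samples, which
keeps the max from being noise-inflated but still biases it upward on noisy
records (on the synthetic cohort β_bend averages ~0.17 against a fitted
~0.13 — the max-of-derivative statistic inherits the noise ceiling, and the
measured cohorts show the same ordering).

## Trajectory and kymograph estimators

- Steady state: θ_f and σ(θ_f) are the mean and standard deviation of
  θ_tip over the last 5 h of the record.
- Time to equilibrium: first entry of θ_tip into θ_f ± max(σ, 1e-3 rad).
  A "sustained" mode (first sample after which every later sample stays in
  the band) is available but degenerate for noisy records: samples keep
  leaving a one-standard-deviation band by construction, pinning the time
  to the end of the record. The σ floor keeps the band non-empty for
  noiseless synthetic data. Note that at the overdamped cohort means the
  slow decay mode is ~0.5/τ, so trajectories are still ~0.1 rad short of
  vertical after 24 h — θ_f is a measured plateau, not exactly π/2.
- Growth-zone length: |∂κ/∂t| is re-indexed by distance from the tip
  d = L(t) − s (linear interpolation onto a uniform 10 µm grid), averaged
  over the response (t < τ_eq, bins with ≥ 50% time coverage), and L_gz is
  the largest distance at which the profile still exceeds 5% of its spatial
  mean. The magnitude is used because bending reversals would cancel in a
  signed mean. On model kymographs this recovers L_gz to one grid cell plus
  half a frame's growth (v_g Δt/2).
- Shape scores: both centerlines are resampled to a common 10 µm arc-length
  grid from the base, truncated to the shorter organ (>10% length mismatch
  is rejected); the distance score is the mean point distance normalized by
  r, the angle score the mean absolute tangent-angle difference in degrees.

## Synthetic experiments

The generator emulates the standard protocol: vertical growth, then
horizontal tilt (θ₀ ≈ 0, stimulus at π/2), one frame every 10 min for 24 h
(145 samples). Per-root parameters are drawn independently — truncated
normals (positive support) at the wild-type means/spreads r = 65 ± 11 µm,
L_gz = 0.60 ± 0.14 mm, v_g = 0.13 ± 0.04 mm/h, β = 0.12 ± 0.06,
γ = 1.6 ± 1.0, and a half-normal θ₀ of scale 0.05 rad for placement
scatter. Measurement error is additive i.i.d. Gaussian angle noise,
default σ = 0.02 rad (~1°), a magnitude that leaves R² > 0.9 attainable as
in measured cohorts. All randomness flows through one seeded generator.

What the generator does *not* emulate: temporally correlated tracking
error, non-uniform curvature within the growth zone, growth-rate
fluctuations, per-root deviations from linear growth, or circumnutation.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to every
feature of real image-derived angles.

## Default problem sizes

The self-tests run the oracle-vs-reduction comparison on a 3×3×2 parameter
grid at 400 material points over eight growth-zone turnovers, a 100-replicate
noisy recovery study, and a 60-root cohort for the response-duration
statistic; the acceptance study uses a 114-root cohort. These sizes give
population statistics stable to a few percent while keeping a full run in
the minutes range on one CPU.

## Known limitations

- Planar shapes only; θ_g is a parameter but all defaults assume
  horizontal gravistimulation.
- The fitter assumes the record starts at the tilt (t = 0 ⇒ K = k = 0).
- The exponential-growth comparison model's apical variant is qualitative
  only (see above); no closed form is attempted.
- The growth-zone estimator assumes curvature change is confined to a
  single apical zone; multiple bending zones are out of scope.
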