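# Methods

## The model

`exotaxis` simulates chemotaxis guided by discrete, diffusible signal
packets (exosomes) rather than by a smooth chemoattractant gradient.  A
*leader* cell moves ballistically in +x at speed v0 and converts a fixed
molecular budget ν (molecules/min) into exosomes: packets are released at
the leader's current position as a Poisson process of rate ν/n̄, each
carrying an integer cargo n_i ~ Poisson(n̄).  Increasing the mean cargo n̄
therefore trades packet frequency for packet payload at a fixed molecular
flux.

Packets diffuse isotropically (per-axis Gaussian increments of variance
2DΔt), may degrade as a first-order process with timescale 𝒯 (per-step
probability Δt/𝒯), and are absorbed on first arrival within the capture
radius a of the *follower* cell.  Each absorption is a detection event
(t_i, θ_i, n_i): the cargo is passed through a Hill nonlinearity
α_i = n_i^H/(n_i^H + K^H) (half-max at the threshold K; sharper for larger
Hill coefficient H), and the arrival angle θ_i = atan2(y_i − y_f, x_i − x_f)
is remembered with an exponential kernel m_i(t) = e^{−(t−t_i)/τ}.  The
follower's state is the decayed activation total M = Σ α_i m_i and the
decayed direction vector (C, S) = Σ α_i m_i (cos θ_i, sin θ_i).  At every
cell step the follower moves a distance v0Δt_cell along the remembered mean
angle atan2(S, C) with probability M/(1+M), and along a uniformly random
direction otherwise.  The figure of merit is the ensemble-mean drift
v̄ = ⟨x_f(T) − x_f(0)⟩/T, bounded by v0.

A closed-form 1D reduction assumes the follower walks along the trail of
packets the leader leaves behind, replaces each activation by the
mean-cargo value ᾱ = n̄^H/(n̄^H + K^H), and counts the packets met within
one memory time, N ≈ v̄τν/(v0 n̄).  Solving the self-consistency
v̄/v0 = M/(1+M) with M = ᾱN gives

    v̄/v0 = max(0, 1 − φ),   φ = βx(1 + x^−H),   x = n̄/K,  β = K/(τν).

For H > 1, φ is minimized at x* = (H−1)^{1/H} (so the optimal packet size
is of order the detection threshold, n̄* ≈ K), with peak velocity
1 − β·H/(H−1)·(H−1)^{1/H} → 1 − β for H ≫ 1.  `theory.self_consistent_solve`
re-derives the piecewise form numerically (Brent root for φ < 1, Newton on
the φ ≥ 1 branch, where plain fixed-point iteration would converge only
algebraically) and agrees with the closed form to 1e-10; `mc_1d_simulate`
is a direct Monte Carlo of the reduced model and quantifies the quality of
the ᾱ and encounter-counting approximations.

## Default parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| a | capture radius | 10 | μm |
| ν | molecular secretion rate | 350 | molecules/min |
| n̄ | mean cargo per exosome | 50 | molecules |
| v0 | leader/follower speed | 3.4/60 ≈ 0.0567 | μm/min |
| D | exosome diffusivity | 250 | μm²/min |
| τ | memory time | 5 | min |
| K | detection threshold | 25 | molecules |
| H | Hill coefficient | 3 | — |
| 𝒯 | degradation time | ∞ (none) | min |
| Δt_exo | exosome substep | 0.1 | min |
| Δt_cell | cell step | 40 | min |
| T | total time | 1440 | min |
| l0 | initial separation | 10 | μm |

All internal arithmetic is in micrometres and minutes; speeds quoted in
μm/hr convert with `physics.convert_speed`.  Δt_exo ≲ a²/D and
Δt_cell ≲ a/v0 are enforced as warnings.  The defaults for n̄ and H are the
reference cargo (n̄0 = 50) and the cooperative regime (H = 3) used in the
headline cargo-scaled-diffusivity comparison; every preset and acceptance
configuration sets both explicitly.

## Discretization and conventions

* Two timescales: within each cell step (Δt_cell = 40 min = 400 exosome
  substeps) the follower is held at its last position; the leader's
  position is evaluated exactly (l0 + v0·t) at every substep.  Substep
  order: leader update → secretion → diffusion → wall reflection →
  degradation → detection.  Newborn packets take a diffusion kick in their
  birth substep and are first eligible for detection at its end; a packet
  born inside the capture disc is simply detected at the next check.
* Detection is evaluated at substep resolution against the follower's
  piecewise-constant position; there is no within-substep (Brownian-bridge)
  crossing correction, so detection is undercounted once √(2DΔt_exo)
  becomes comparable to a (at D = 1000 μm²/min, √(2DΔt_exo) = 14 μm > a).
  This is a property of the discretized model itself and is left
  uncorrected deliberately.
* Angles are kept in (−π, π]; the arrival angle uses the quadrant-aware
  two-argument arctangent, with the (measure-zero) center hit assigned
  angle 0.  If the direction vector cancels exactly (S = C = 0) while
  M > 0, the step falls back to the uniform branch.
* Memory is held as three lazily decayed accumulators — exactly equivalent
  to the full event list for a shared exponential kernel; an event-list
  reference implementation is retained and tested against it.
* Degradation applies each substep with probability Δt_exo/𝒯, giving the
  survival curve (1 − Δt/𝒯)^{t/Δt} → e^{−t/𝒯}.
* Reflective walls at y = ±L fold both exosome and follower y-coordinates
  by mirror reflection.
* The 1D Monte Carlo launches the leader from the follower's position
  (l0 = 0).  Leader and follower share one speed, so any positive head
  start would put the trail permanently out of reach; the reduced theory
  describes the walk *along* the trail.  Its default step (1 min) sits well
  below τ so the discrete walk approximates the quasi-continuous memory
  integration the closed form assumes.

## The production kernel and its far-field accelerator

The per-substep reference engine (pure numpy over the public field/memory
operations) is exact to the model definition but too slow for day-long,
half-million-particle ensembles.  The production path is a compiled kernel
that is statistically equivalent, with one numerical device: a particle at
distance d from the follower may traverse k substeps in a single Gaussian
jump (variance scaled by k), skipping the k−1 intermediate detection
checks.  Skipped checks could only matter if an intermediate position
entered the capture disc, which requires a walk excursion of magnitude
r = d − a; a union bound over the exact per-step radial tails,

    P(any of k−1 intermediate positions within the disc)
      ≤ (k−1) exp(−r²/(2(k−1)σ²)),     σ² = 2DΔt_exo,

is kept below ε = 1e-5 per jump (k is read from a lookup table over
quantized r/σ, rounded conservatively; the jump endpoint is always
checked).  A skipped check leaves the particle alive and detectable at
later checks, so even the bounded-probability events are delays rather
than losses.  Jumps are disabled whenever walls are active (endpoint
folding does not commute with intermediate checks) and for immobile
particles, which are resolved analytically within a window.  Displacement
noise is drawn from buffered float32 SFC64 streams; structural randomness
(secretion counts, cargos, degradation, direction choices) uses a separate
PCG64 stream, both spawned deterministically from the run seed, so runs
are bit-reproducible for a given (config, seed).  The fast and reference
paths are cross-validated statistically in the test suite.

Ensembles use seeds base_seed + i, and sweeps reuse the same seed sequence
at every grid point (common random numbers), so grid points differ only
through the swept parameter.  Grid argmaxes report the grid value with the
highest ensemble-mean velocity, ties broken toward the smaller value, with
the one-grid-step bracket attached.

## Diffusivity physics

`physics.stokes_einstein_D` evaluates D = k_BT/(6πη r) with r the
hydrodynamic radius (a diameter reading is available as an option), default
T = 293 K and η = 1.0 mPa·s; radii of 150 and 30 nm give ≈86 and
≈429 μm²/min, the physiological band for exosome-sized particles.
`physics.optimal_D_prediction` matches the diffusive spread to the
retreating source, √(4Dt) = l0 + v0t at t = a/v0, giving
D* = v0(l0 + a)²/(4a); the alternative timescale t = a²/D yields a negative
root for l0 > 2a and is discarded.  The cargo-scaled transport mode applies
D(n̄) = D0(n̄0/n̄)^{1/3} (volume ∝ cargo) at the scenario level; a
per-exosome variant (D_i from each realized cargo) exists and is off by
default.

## Problem sizes, and what the reduced scale does and does not show

Publication-quality curves for this model use thousands of runs per grid
point; the packaged ensembles use 100-200 runs per point with common random
numbers, which resolves the qualitative structure (interior versus boundary
optima, monotone trends) but not sub-percent velocity differences between
neighbouring grid points.  The synthetic scenarios are exactly the model's
own study conditions — there is no external data — so passing tests
demonstrate internal consistency of the implementation and the
reproducibility of the model-level claims at reduced scale, not agreement
with any particular experimental system.

Two model-level findings from the packaged sensitivity runs are worth
stating explicitly:

* With the leader starting one capture radius away (l0 = 10 μm), the
  velocity-versus-diffusivity curve is a statistical plateau across
  D ≈ 25-150 μm²/min (pairwise common-random-number differences consistent
  with zero at ~1e-4 μm/min resolution), falling off only toward D = 0 and
  D ≳ 500.  This is consistent with the matching-time prediction, which
  puts D*(l0 = 10) ≈ 0.6 μm²/min — below the first nonzero grid point: at
  this separation essentially any moderate diffusivity delivers the signal
  before the leader escapes.  A sharp interior optimum near 100 μm²/min
  would require a substantially larger initial separation
  (D* = 100 μm²/min corresponds to l0 ≈ 255 μm).  The grid argmax reported
  for the default sweep therefore sits anywhere on the plateau, depending
  on the seed.
* With no degradation (𝒯 = ∞), the H = 1 velocities at n̄ = 1 and n̄ = 5
  are nearly tied (the 1D theory puts their difference at β·Δx ≈ 0.2% of
  v0); the single-molecule optimum is systematically favoured but only by
  ~1-2 combined standard errors at 200 runs.  Finite degradation times
  sharpen the distinction.

## Known limitations

* No advection, matrix anisotropy, exosome-exosome interaction, or
  receptor-level binding kinetics; the follower is a point detector with an
  idealized absorbing rim.
* The follower's step length is fixed (v0Δt_cell); only its direction is
  stochastic.
* Velocities are measured along the leader's heading; the leader's path is
  a straight line by construction.
* The closed-form layer inherits the mean-activation and
  encounter-counting approximations; the 1D Monte Carlo quantifies the
  residual (≈ 0.01-0.05 v0 at small β, larger near φ → 1).
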