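# Methods

This note documents the models implemented in `ddssa`, the conventions and
numerical choices behind them, what the synthetic benchmarks do and do not
show, and the design decisions taken where the methodology leaves room.

## 1. The two-step methodology

A diffusion-driven event (translocation between compartments, association of
a diffusing pair) is summarised by the cumulative distribution of its
arrival time, P(t_a ≤ t).  Once tabulated, that distribution replaces the
spatial detail entirely: a purely temporal delayed stochastic simulation
draws each event's delay from it by inverse transform.  Accuracy therefore
rests on the first step — the distribution must be generated under initial
conditions representative of the process being modelled — while the second
step is exact given the distributions.

### Delay distributions

`DelayDistribution` stores a tabulated CDF on a time grid, *conditional on
arrival*.  Molecules that never perform the event within the generating
horizon are bookkept separately as `arrival_mass`; engines first draw
arrival vs non-arrival as a Bernoulli(arrival_mass) trial, and a
non-arriving molecule stalls in transit (still observable and, under M2,
still poachable) without ever completing.  This convention keeps every
tabulated CDF proper while representing defective first-passage laws.  The
generating horizon should be long enough that `arrival_mass` is close to 1
for events that are certain in the long run; the benchmark workflows use
horizons of 3× the comparison window for association/export distributions.

Sampling is by generalized inverse.  For smooth CDFs (PDE-derived,
SSA-mean-derived) the inverse is linearly interpolated between grid points;
empirical CDFs evaluate as right-continuous steps but are sampled with
linear interpolation by default (`interp="step"` reproduces support points
exactly, which is what the constant-delay limit uses).

### Spatial sources

**Particle simulator.**  A minimal off-lattice Brownian simulator in the
single-particle-tracking tradition: each time step runs particle motion,
neighbour finding, then reactions.

* *Cube Brownian motion.*  Per-axis Gaussian displacements with nominal
  standard deviation σ = √(2 D Δt), truncated by rejection to the cube of
  half-width 3σ around the current position.  Truncation removes variance,
  so the raw draw scale is inflated by a constant (solved numerically once,
  ≈1.0136) such that the truncated step variance equals 2 D Δt exactly;
  the measured mean-squared displacement then matches 6 D t to within
  sampling error.  The truncation width and variance-preserving calibration
  are this package's convention; only the cube construction itself is
  standard.
* *Membranes.*  Cell and nucleus are concentric spheres (defaults 7.81 µm
  and 4.29 µm, typical of a human carcinoma cell).  A proposed move that
  crosses a membrane translocates with the per-(species, membrane)
  permeability (default 1 for the nuclear membrane, 0 for the outer one);
  a failed or forbidden crossing is *resampled* — the displacement is
  redrawn until the particle stays in its compartment — rather than
  specularly reflected.  At the small time steps used (10⁻³ s, 10⁻⁴ s for
  fast diffusion) the two conventions are distributionally equivalent;
  resampling avoids constructing reflections off curved surfaces.
* *Reactions.*  All particle pairs within a cutoff radius R (inclusive,
  ≤ R) are candidate reactants, found with a k-d tree (equivalent to
  binning with bin size ≥ R over adjacent bins).  Each candidate pair
  fires with a per-step probability p ≤ 0.5, particles are processed in
  randomized order with at most one reaction per particle per step, and
  products are placed at the pair midpoint.  p is a per-channel
  configuration knob; `reaction_probability` provides a well-mixed
  Smoluchowski-style conversion from a rate constant, documented as
  approximate because diffusion limitation and repeated-contact
  correlations are ignored.  Unary conversions fire per particle with
  probability 1 − e^{−kΔt}.  Membrane-bound species are constrained to the
  outer sphere surface (a step is proposed in 3D and projected back).

**1D first-passage problems.**  `solve_arrival_pde` integrates the
advection–diffusion equation on [0, L] with a Crank–Nicolson finite-volume
scheme: absorbing boundaries are Dirichlet p = 0 at the wall face
(half-cell gradient), reflecting boundaries zero-flux.  P(t_a ≤ t) is
accumulated from the discrete absorbing-face fluxes, which matches the
operator's boundary term exactly, so remaining + absorbed mass is conserved
to round-off at every step (the solver reports the residual, typically
< 1e−12).  The reported dP/dt uses a second-order one-sided wall gradient.
The point initial condition is split over the two cells bracketing x₀ so
its centroid is exact; a single-cell delta biases every eigenmode by up to
Δx/2, which is visible in the early-time pdf.  A problem with D = 0 (or
with no absorbing boundary) absorbs nothing and is rejected with an error,
since the arrival CDF does not exist.

`random_walk_1d` runs ±step lattice walks with an absorbing wall at 0 and a
reflecting wall at L, on the physical clock Δt = step²/(2D).  The kernel
uses an exact block acceleration: from lattice position m the walk cannot
touch the absorbing site (nor fold past the reflecting wall onto it) within
j = min(m, 2N − m − 1) steps except exactly at the block end, so the net
displacement over j unconstrained steps — 2·Binomial(j, ½) − j, folded at
the reflecting wall by the reflection principle — has the exact marginal
law and absorption can be detected block end by block end without bias.
This turns ~10⁷ steps per walker into ~10³–10⁴ binomial draws and makes the
10,000-walker benchmark run in seconds.

**SSA means.**  For well-mixed channels, the mean time course of the
isolated reaction (reactant depletion or product accumulation fraction,
normalised to its final change) *is* the per-molecule event-time CDF;
`cdf_from_ssa_mean` enforces monotonicity up to a small Monte-Carlo
tolerance and rejects flat time courses.

### The delay-SSA engine

The engine extends the direct method: delayed channels fire like ordinary
channels but enqueue their state change at t + τ.  If a scheduled
completion falls inside the next exponential waiting time, the engine
ignores the drawn waiting time and continues from the completion.  All
delayed reactions are consuming: reactants move from the free pool to an
in-transit pool at selection and products appear at completion.  Observable
counts report free + in-transit molecules — a molecule diffusing towards
the nucleus is still physically present in its source compartment — which
also makes the conserved mass an exact integer invariant checked in tests.

* **M1** draws delays from tabulated CDFs; delayed channels run at a large
  propensity constant (default 10⁴ s⁻¹ per molecule, configurable) so the
  waiting time is negligible against the delays.  Doubling this constant
  changes benchmark trajectories by less than the Monte-Carlo band (tested),
  which is the premise of the construction.  A channel with an explicitly
  set rate constant keeps it (rate tuning, see Scenario 6 below).
* **M2** lets non-delayed channels draw in-transit reactants: each reactant
  slot poaches with probability in_transit/(free + in_transit), cancelling
  a uniformly random pending entry holding that species (molecules in a
  well-mixed pool are indistinguishable).  The committed molecule is
  consumed by the non-delayed reaction instead.  M2 is restricted to unary
  delayed channels: for a poached *binary* delayed reaction the fate of the
  second reserved reactant is not defined by the methodology, so such
  configurations are rejected rather than silently guessed.
* **M3** replaces propensities entirely: every channel must be delayed;
  each selection round draws one delay per feasible channel (fresh draws
  every round, avoiding stale-minimum bias) and the minimum fires,
  consuming its reactants; when nothing is feasible, time jumps to the next
  completion.  Ties break to the lowest channel index.  For CDFs derived
  from exponential kinetics this reproduces the SSA's branching fractions
  k₁/(k₁+k₂) exactly (tested at three rate ratios).
* **M4** is time-windowed restriction of the inverse-transform uniform:
  while a rule is active, u is drawn from a sub-interval of [0,1), which
  conditions the delay on a quantile range (u ∈ [0, 0.5) restricts draws
  below the median — equivalent in distribution to truncating the CDF,
  property-tested).  Overlapping active rules for one channel are an error.
  The generalisation to full piecewise distribution switching is also
  supported: a channel's delay source may be a list of
  ((t_start, t_end), distribution) pairs selected by the time of the draw.

Two independent random streams drive the engine: one for the SSA core
(waiting times, channel selection, poaching) and one for delay draws.  This
draw discipline makes the core path invariant to how many delay draws a
mode consumes, so M1 with a degenerate distribution is *path-identical* to
the constant-delay DSSA under a shared seed (asserted in tests).  The
pending queue is a binary heap with lazy (tombstoned) cancellation.

### Deterministic counterparts

The five-ODE baseline treats both translocations as unimolecular
mass-action steps — it has no representation of transport lags, which is
exactly why it cannot match spatial references with pronounced first-passage
structure.

The buffered DDE gives each delayed step a buffer holding molecules in
transit:

    A_c' = −k₁ A_c                        B₁' = k₁ A_c − k₂ B₁(t−τ₁)
    A_n' = k₂ B₁(t−τ₁) − k₃ A_n B_n       B_n' = −k₃ A_n B_n
    B₂' = k₃ A_n B_n − k₄ B₂(t−τ₂)        C_n' = k₄ B₂(t−τ₂) − k₅ C_n
    B₃' = k₅ C_n − k₆ B₃(t−τ₃)            C_c' = k₆ B₃(t−τ₃)

This chain is the unique one-buffer-per-delayed-reaction form with six rate
constants and three delays whose A-chain mass
A_c + B₁ + A_n + B₂ + C_n + B₃ + C_c telescopes to a constant exactly (an
algebraic identity, tested at random states).  Two properties matter in
practice: (i) each buffer equation b' = in − k b(t−τ) is oscillatory and
unstable for k τ > π/2, so fits bound rates and delays jointly (an unstable
parameter set scores infinite fitness and is discarded); (ii) because
outflow depends on the *delayed* buffer value, buffers can transiently go
slightly negative — allowed by default, with an optional clamp flag for
fitting stability that warns when it engages.  For comparisons with
observable species, buffered molecules are counted with their physical
identity (A_c + B₁, A_n + B₂, B_n + B₂, C_n + B₃, C_c).

Integration is method-of-steps with fixed-step classical RK4 and cubic
*Hermite* interpolation of the stored solution (values and nodal
derivatives — true dense output), which keeps delayed-argument lookups
fourth-order accurate right up to the newest completed step; halving the
step changes the solution by < 1e−6 sup-norm from Δt = 0.025 s on the
benchmark parameter sets.  Δt should not exceed the smallest positive
delay; delays below Δt fall back to a clamped lookup (documented, not
recommended).  Zero delays short-circuit to the current stage value, giving
the exact ODE limit, and DDE solutions converge to that limit as τ → 0
(tested over a refinement sequence).

### Evolution-strategy fitting

A textbook self-adaptive (μ+λ) ES: per-coordinate log-normal step-size
mutation (learning rates 1/√(2n) global, 1/√(2√n) per coordinate), elitist
survival of the best μ from parents ∪ offspring, reflection at box bounds,
independent restarts with the overall best returned.  Defaults μ = 5,
λ = 35, 100 generations, 10 restarts; fitness is the least-squares error
against the reference at a sample set of time points (default: every second
grid point).  The two-phase workflow `manual_then_es` injects a manual
guess as one parent of every restart, so elitism guarantees the result is
never worse than the guess.  The population sizes and operators are this
package's declared choices, not inferred from elsewhere.

## 2. Benchmark scenarios and delay splitting

The registry (`make_scenario(1..10)`) carries the published defaults:
clustered initial conditions are 1000 molecules in a 0.5 µm sphere 7 µm
from the cell centre; diffusion constants 10⁻⁷ or 10⁻⁹ cm²/s per species;
rate constants k = 0.1 s⁻¹ for the unary conversions; Scenario 6 variants
with (1000, 1000) or (1000, 500) translocating molecules, 1000 nuclear
partners, and the tuned association rate k = 0.015 s⁻¹ as an explicit
override; Scenario 10 with k₁ ∈ {10⁻⁵, 10⁻¹, 1}, k₂ = 1.  Particle runs
use Δt = 10⁻³ s and a pair cutoff of 0.1 µm with p = 0.5 (the cutoff/p
pairing is this package's choice; only their product-scale is constrained
by any published number).  Where a count is not printed anywhere (the
nuclear partner count in Scenarios 4–5), the registry defaults to 1000 for
consistency with Scenario 6.

Delay splitting decomposes a multi-stage scenario into one generator per
delayed channel:

* *arrival* — run the isolated translocation from the scenario's own
  initial placement and record first-passage times.  Used for every
  translocation τ, including competing-reaction scenarios, where feeding
  the competition-conditioned arrival statistics back into the engine would
  double-count the competition.
* *frozen_replay* — record the positions at which an upstream event
  happened (nuclear-entry coordinates, association midpoints), seed the
  reactant there all at once, and record the downstream event times.  This
  carries the documented simplifying assumption that all upstream arrivals
  happen simultaneously; it is accurate when the upstream arrival spread is
  small against the downstream time scale and degrades gracefully
  otherwise (see §4).
* *timecourse* — read the CDF off a monotone species time course of the
  full spatial run (Scenario 9's association, inferred from the partner's
  depletion).
* *ssa_mean* — mean SSA runs of the isolated well-mixed channel
  (Scenario 10; 20 runs by default).

## 3. Benchmark problem sizes

The shipped benchmarks are desk-scale versions of the full analyses,
chosen so the statistical assertions stay meaningful:

* The 1D first-passage comparison runs at full scale (10,000 walks,
  L = 3.52 µm, 1 nm steps, start 0.81 µm from the reflecting wall) thanks
  to the block-accelerated kernel; the KS acceptance bound is the 1%-level
  two-sample value 1.63/√n.
* The translocation self-consistency loop uses 100 particles and 10 engine
  runs; the acceptance envelope is 3 binomial standard errors plus one
  molecule of grid slack.
* The deterministic comparison (Scenario 5's chain) runs 200 + 200
  molecules with the published diffusion profile (fast cytosolic A_c at
  10⁻⁷ cm²/s, slow nuclear species at 10⁻⁹ cm²/s) over 100 s.  This
  profile is the regime the methodology targets — arrival is fast but the
  nuclear stages carry pronounced transport lags — and at the same time the
  regime where the frozen-replay assumption is sound (arrival spread ≪
  association time scale).  The reference is the mean of 8 particle runs;
  both deterministic models get the same ES budget (μ=5, λ=20, 30
  generations, 2 restarts).  The DDE's manual phase, mirroring the
  manual-estimate-then-fine-tune workflow, tries two natural candidates and
  keeps the better fit: (i) the fitted ODE embedded at zero delays with fast
  buffers (the DDE nests the ODE, so elitism guarantees the DDE fit is
  never worse than the ODE's), and (ii) delays set to the observed lags
  (10% quantiles of the delay distributions) with stage rates from the
  residual spreads.  The ES phase around each guess is a local fine-tune
  (initial step sizes 1/50 of the parameter spans).
* The competing-association scenario runs 100 + 50 translocating molecules
  against 100 partners at 10⁻⁷ cm²/s with clustered A_c, an 8-run particle
  reference, and association CDFs generated to a 200 s horizon so they
  saturate.  At this scale the *D-channel* association is the dominant
  (over-selected) delayed reaction, so the trial-and-error rate tuning that
  the methodology prescribes is applied to it, as a small grid scan
  minimising the steady-state deviation.  The dDSSA steady state is read at
  engine quiescence (5× the reference window, by which every in-transit
  completion has been released) and compared species-by-species against the
  particle steady state; the tuned deviation is well under the ±2-molecule
  acceptance band, the untuned one is reported alongside.

## 4. What the benchmarks do and do not show

The synthetic sources and the engines share the same particle model, so the
benchmarks validate the *methodology* — that tabulated first-passage
distributions capture spatial dynamics inside a temporal simulation — not
the particle model's fidelity to any real cell.  Real data differ in ways
the benchmarks do not probe: crowding and anomalous diffusion, non-spherical
geometry, active transport (the PDE's advection term is implemented but no
benchmark exercises it), and measurement noise in experimentally derived
CDFs.

The known accuracy limits are inherent to fixed distributions, not to the
implementation: when the spatial configuration feeding an event changes
materially over the simulation (strongly coupled delayed reactions, late
associations under partner depletion, translocation feedbacks), a single
CDF per channel is an approximation.  The in-methodology remedies — M4
windows/truncation, piecewise distributions, rate tuning of the dominant
delayed channel — are implemented and benchmarked where the scenarios call
for them; state-dependent (position-conditioned) delay draws are out of
scope.

## 5. Smaller conventions

* Channel order is declaration order; together with the dual-stream draw
  discipline, a fixed seed gives bit-identical trajectories.
* Pair distance is inclusive (≤ cutoff) to avoid zero-measure surprises.
* Dimerization propensity uses the combinatorial count k·n(n−1)/2; the
  particle engine pairs a species with itself for the same channel.
* Trajectories are recorded event-by-event (stochastic: right-continuous
  step interpolation) or on the integrator grid (deterministic: linear) and
  resampled onto common grids for comparison; the total relative error is
  Σ_s |A_s(t) − B_s(t)| divided by the reference's total molecule count.
* Positions are micrometres, diffusion constants cm²/s (converted
  internally), times seconds.  CSV round-trips write floats as %.17g and
  read with round-trip precision, so stored distributions are bit-exact.
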