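# ddssa — spatial effects as probability-distributed time delays

Spatially resolved stochastic simulators (single-particle tracking of
Brownian molecules in a cell) portray translocation and diffusion-limited
association faithfully, but at a cost that makes biologically interesting
time spans unreachable.  Well-mixed temporal simulators (the Gillespie SSA
and its delayed variants) are orders of magnitude cheaper but blind to
geometry and diffusion.  `ddssa` implements the bridge between the two, for
modellers of compartmentalised signalling processes:

1. **Distribution fitting.**  Every diffusion-driven event — a nuclear
   translocation, a pair association — is characterised by the cumulative
   distribution of its arrival (first-passage) times, P(t_a ≤ t).  That CDF
   is obtained once, from a single inexpensive spatial source: a bundled
   off-lattice Brownian particle simulator with semi-permeable spherical
   membranes (`ddssa.particles`), a 1D advection–diffusion solve
   ∂p/∂t = D ∂²p/∂x² − v ∂p/∂x with mixed absorbing/reflecting boundaries
   and P(t_a ≤ t) = 1 − ∫ p dx, a 1D lattice random walk, or a mean SSA
   time course (`ddssa.delays`).
2. **Delayed stochastic simulation.**  The CDFs feed a delay-SSA in which
   each delayed reaction draws its delay by inverse transform
   (`ddssa.engine`).  All delayed reactions are *consuming*: reactants are
   reserved when the channel fires and products appear at the scheduled
   completion, so counts never go negative.  Engine modes cover the
   methodology's modifications: distribution-drawn delays at a high channel
   rate (**M1**), cancellation of scheduled translocations by competing
   non-delayed reactions (**M2**), selection by *delay minima* instead of
   propensities for fully delayed networks (**M3**), and time-windowed or
   truncated delay distributions (**M4**).
3. **Deterministic counterparts.**  For the high-copy-number regime, a
   buffered delay-differential model gives each delayed step a buffer
   species holding molecules in transit (nine parameters: rates k₁..k₆ and
   delays τ₁..τ₃; the chain mass is conserved exactly), alongside a plain
   five-ODE baseline (`ddssa.dde`).  Parameters are estimated against
   reference time courses by a self-adaptive (μ+λ) evolution strategy with
   least-squares fitness (`ddssa.fitting`).

`ddssa.scenarios` bundles ten benchmark reaction–diffusion scenarios
(spherical cell of radius 7.81 µm, nucleus 4.29 µm) with their
delay-splitting recipes — the decomposition of a multi-stage process into
separate single-event spatial runs, each yielding its own τ distribution —
and `ddssa.benchmarks` packages the end-to-end analyses.

## Worked example

Two unary channels A → B (k₁ = 0.1 s⁻¹) and A → C (k₂ = 1 s⁻¹) compete for
1000 A molecules.  Their delay distributions are tabulated from mean SSA
runs of each isolated reaction, and the delay-minimum engine (M3) replaces
propensity-based selection entirely:

```sh
$ python examples/03_competing_channels_m3.py
tau1: median 6.97 s (from mean SSA time course)
tau2: median 0.70 s (from mean SSA time course)

20-run mean:  B_inf = 91.1   C_inf = 908.9
SSA branching: 1000 k1/(k1+k2) = 90.9
-> delay-minimum selection reproduces the stochastic branching ratio
```

The medians are the half-lives of the two isolated decays (ln 2/k), and the
final B count matches the SSA's branching fraction k₁/(k₁+k₂) within
sampling error — the engine recovers exact well-mixed kinetics as a special
case while its delay distributions may equally come from spatial
simulations.

The other example scripts each demonstrate one capability end to end:
`01` first-passage CDFs from walks vs the diffusion PDE, `02` a particle →
CDF → delay-SSA translocation loop, `04` the buffered DDE with exact mass
conservation, `05` evolution-strategy rate recovery.

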