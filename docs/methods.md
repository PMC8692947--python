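# Methods

## Neuropercolation model

The substrate is the discrete torus ℤ²_N with its 4-neighbor short edges.
Long edges are sampled independently for every unordered vertex pair at
torus L1 distance d ≥ 2 with probability p_d = min(1, c/(N·d^α)).  Pairs at
distance 1 are excluded because they are already short-edge neighbors and
the update rule should count each neighbor once; the clamp handles small
N·d^α with large c.  L1 is used as "distance on the lattice" because it is
the geodesic metric of the short-edge topology.  Sampling enumerates one
canonical representative of each offset ±δ (with a half-lattice mask for
the self-inverse offsets that exist on even tori), so each pair is drawn
exactly once and rebuilding with the same (N, c, α, seed) gives an
identical edge set.

The expected long degree λ(N, c, α) is computed by exact shell
enumeration, Σ_{d≥2} S(d)·p_d with S(d) the true torus shell size — not
the planar 4d approximation, which fails once d exceeds N/2.  For α = 1
this gives λ → 4 ln 2 · c ≈ 2.77 c as N grows (the continuum integral of
1/(x+y) over the wrapped quadrant), a point worth noting because the
planar approximation suggests 2c.  `solve_c_for_lambda` inverts the
relation so simulations and mean-field theory meet on a common λ axis;
whether that axis matches other normalizations in the literature is not
determinable here, so the mean-long-degree convention is documented and
used throughout.

Dynamics: the synchronous rule χ_v(t+1) = 𝟙(Σ_{u∈N(v)} χ_u(t) ≥ k), with
v's own state excluded.  The optional noise ε flips each computed state
independently (post-update); ε = 0 recovers the deterministic rule
exactly and is the default everywhere.  Runs terminate on the absorbing
uniform states (the fully active lattice counts as absorbing only when
k ≤ minimum degree), on a repeat of either of the previous two states
(synchronous threshold dynamics admits non-uniform fixed points and
period-2 blinkers; both are reported as `cycle`), or on `max_steps`.

## Mean-field map and critical probability

The annealed closure replaces each vertex's neighborhood by independent
Bernoulli(ρ) draws over 4 short neighbors plus a Poisson(λ) long degree:

    F(ρ) = Σ_j Pois(j; λ) · P(Binomial(4+j, ρ) ≥ k),

with the Poisson truncated at tail mass 10⁻¹² and renormalized.  Fixed
points of F are located by a sign-change scan on a 4001-point grid plus
Brent refinement (default tolerance 10⁻⁶); stability comes from the local
slope.  p_c is the smallest interior unstable fixed point — the basin
boundary — with sentinels 0 (extinct state unstable, any density spreads)
and 1 (no interior boundary, activity always dies).  For k > 4 several
interior unstable points can coexist; the smallest is reported and the
solution flagged.

At λ = 0 the map has closed forms used as oracles: k=1 gives
F = 1−(1−ρ)⁴ > ρ on (0,1) so p_c = 0; k=4 gives F = ρ⁴ < ρ so p_c = 1;
k=3 gives F = 4ρ³−3ρ⁴ with interior root (1+√13)/6 ≈ 0.76759.

### Monte-Carlo estimator and what "success" means

`monte_carlo_critical` estimates the finite-size critical density with a
quenched, coupled design: each replicate owns one sampled graph and one
fixed vector of per-vertex uniforms u, and the initial state at density p0
is {u < p0}.  Initial sets are then nested in p0 and, the threshold rule
being monotone in the state, the outcome is monotone too — every
replicate has a deterministic critical density found by bisection.  The
estimate is the median across replicates; the confidence interval comes
from binomial order statistics.  This is distributionally equivalent to
probing success fractions at each bisection step but strictly lower
variance and immune to non-monotone probe noise.

A run counts as "spread" when its final density reaches `success_rho`,
default 0.5.  The default deliberately classifies the *basin*: above
threshold the literal synchronous rule grows to a frozen state with a few
stubborn inactive holes (final ρ ≈ 0.96–0.99 at N=64), so demanding
ρ ≥ 0.99 would measure the hole-free-coverage threshold — for k=3, λ=1 at
N=64 that lies near 0.79, far above the basin boundary near 0.50 that the
mean-field p_c describes.  The cutoff is configurable for anyone who wants
the coverage threshold instead.

### Where mean-field agrees with simulation, and where it cannot

For k=3 the quenched estimates at N=64 track the mean-field p_c within
about 0.03 at λ ∈ {0.5, 1} and 0.05–0.06 at λ=2.  For k=2 the agreement is
qualitatively different: the finite-lattice threshold (≈0.04–0.09) sits
systematically *below* the annealed prediction (≈0.08–0.17) because
2-neighbor-style growth proceeds by local nucleation — small seeds grow by
rectangle-edge completion, a mechanism invisible to a one-density closure
— and the gap widens with N (−0.054 at N=32 → −0.062 at N=64 for λ=1).
This is a property of the model pair, not an implementation artifact; the
test suite asserts the agreement where it holds and the discrepancy is
reported as-is by the acceptance script.

## CAN model

Izhikevich dynamics in the standard regular-spiking parameterization
(a=0.02, b=0.2, c=−65, d=8, v_peak=30; dv/dt = 0.04v²+5v+140−u+I,
du/dt = a(b⁺v−u)), integrated by explicit Euler at dt = 0.1 ms.  The
canonical polynomial forms are used since only the model family is
specified.  The metabolic pair is

    dg/dt = −Ψ₁ + κ·D(t),   dm/dt = −Ψ₂ + Ψ₁,
    Ψ₁ = k_g·g·(1 − m/m_max),   Ψ₂ = k_m·m,

the simplest forms that make Ψ₁ a saturating glycogen→ATP conversion and
Ψ₂ a linear ATP consumption; both pools are clamped to [0, capacity] and
are dimensionless.  D(t) is a sliding-window functional of recent
membrane activity over τ ms.  Because v is negative most of the time, the
raw integral ∫v dt′ is sign-ambiguous as a glutamate proxy; the default
mode is the rectified integral ∫(v − v_ref)₊ dt′ with v_ref = −65 (the
reset value), which is zero at subthreshold rest and positive during
spiking, matching the intended "cumulative effect of spiking".  Raw and
spike-count modes are selectable.

Per-step order is fixed: window drive → metabolic update → b⁺ = ωb + βm
from the updated m → membrane update.  With β = 0 the spiking path is
bitwise independent of every metabolic quantity (b⁺ reduces to ωb
exactly), which the tests assert.

Free parameters have no published values; the defaults were chosen once
so the closed loop operates in the regime the model family describes and
are (units ms⁻¹ where applicable): κ = 5·10⁻⁴, τ = 20 ms, k_g = 0.01,
k_m = 0.005, g_max = m_max = 1.  With sustained spiking, g saturates and
m equilibrates at k_g/(k_g+k_m) = 2/3 on a ≈150 ms timescale, so the
feedback term βm spans [0, 1/3] over the allowed β range — enough to move
b⁺ from 0.20 to ≈0.53 and roughly triple the firing rate.

A useful closed form: the Izhikevich rest state exists while
I ≤ (5−b⁺)²/0.16 − 140, i.e. rheobase 4.0 at b⁺ = 0.2 but ≈0 at b⁺ = 0.27.
The population default I_dc = 2 sits *between* those rheobases, which is
what makes the population bistable: a quiescent group has m ≈ 0, b⁺ = ωb,
rheobase 4 > I_dc, and stays quiescent; a spiking group sustains m ≈ 2/3,
drives b⁺ above 0.27, and keeps itself above threshold.  κ = 0 or β = 0
breaks the loop on either side and collapses the system to monostability.

Populations couple through current-based exponential synapses (decay
5 ms), all-to-all with per-synapse weight w/n (total weight w = 5 by
default; Erdős–Rényi with weight w/(p·n) selectable), plus white current
noise with Euler–Maruyama scaling (amplitude σ = 0.2 by default — small
enough not to ignite the quiescent state over seconds, large enough to
de-trivialize synchrony).  Glycogen is one shared pool per population
(astrocytes service many synapses; the shared pool takes the mean drive
and the mean Ψ₁), ATP is per-neuron; per-neuron glycogen is a flag.  b⁺
uses each neuron's own m.

## Synchrony analysis

Spike trains are smoothed with a unit-mass Gaussian kernel (3 ms default),
mean-subtracted, and converted to instantaneous phases by the Hilbert
analytic signal; R(t) is the mean resultant length across neurons.
Traces without temporal variation carry no phase: if fewer than two
vary, R is reported 0 with a degenerate flag — this is what makes a
silent population read as asynchronous rather than trivially coherent,
and windowed summaries extract phases on the analysis window only.  A
spike-count-correlation matrix is provided as an independent cross-check
metric.

High/low states use a two-threshold Schmitt trigger (defaults 0.6/0.3) to
avoid label chatter; dwell statistics exclude the boundary-censored first
and last runs.  Hysteresis sweeps run the system up then down the same
grid with the end state carried across steps; the loop area is the
integral of |R_up − R_down| and the bistable interval is where the
branches separate by more than Δ_min = 0.2 — well above the 1/√n noise
floor for n ≥ 25.  The cusp scan instead probes each (κ, β) cell from a
charged/coherent and a depleted/quiescent initial condition and compares
long-run mean R; it needs runs long enough for the initial glycogen store
to deplete in the monostable cells (3 s at the default rates), which is
why the scan default is T = 3000 ms.

Phase-cone fitting does a grid search over apex candidates; for each
apex, the slope γ maximizing the mean resultant length R₁ of the
slope-corrected phases e^{i(φ − γr)} is found on a coarse grid in
[−π, π] and refined by bounded scalar minimization, with φ₀ the circular
mean of the corrected phases.  Fit quality is R₁² ∈ [0, 1]: 1 for a
perfect cone, ≈0.04 for uniform random phases on a 16×16 grid (the
normalized excess-concentration alternative (R₁−R₀)/(1−R₀) was rejected
as unstable near R₀ ≈ 0 under the grid-search maximum).  Near-constant
fields (R₀ > 0.999) are flagged degenerate with γ = 0.

## Synthetic data

All test inputs are generated: random small-torus states with a
brute-force enumeration oracle for the update rule; telegraph label
series with known switching rates for the dwell estimator; conical phase
fields with known apex/slope plus wrapped Gaussian noise for the cone
fitter; and a cusp-normal-form map ẋ = p + x − x³ (folds at ±2/3√3) as a
surrogate with an exactly known bistable interval for the sweep
machinery.  These generators emulate the targeted structures, not real
recordings: no measurement noise model, no electrode geometry, no
heterogeneous cell types.  Passing tests therefore demonstrate
correctness of the algorithms on their intended object, not fidelity to
EEG/MEG data.

## Problem sizes and numerical choices

Default test and acceptance workloads use N ≤ 64 lattices, populations of
20–50 neurons, 2–3 s of simulated time at dt = 0.1 ms, 100 synthetic
cones, and 20 Monte-Carlo replicates; these sizes give stable statistics
(order-statistic CIs of ±0.01 on critical densities, ±3% on dwell means)
while keeping a full run in minutes on one CPU.  Halving dt changes
regular-spiking spike counts by < 5%.  Bisection tolerances are 10⁻² for
Monte-Carlo thresholds and 10⁻⁶ for mean-field roots.

## Known limitations

* The annealed mean-field map is a reconstruction; its λ-axis convention
  (mean long degree) and its disagreement with k=2 finite-size dynamics
  are discussed above.
* The relation between the theory's fixed activation probability and the
  initial density is not fully specified by the model family; the package
  treats the critical quantity as the initial activation density.
* Metabolic units are dimensionless; κ, k_g, k_m set relative timescales
  only.
* Whether b⁺ should use per-neuron or population-mean ATP is an open
  modeling choice; per-neuron is the default.
* The phase-cone fitter operates on model-generated or synthetic phase
  fields; mapping simulation output to a cortical "phase field" is an
  interpretive bridge, and no statistical cone classification against
  empirical criteria is attempted.
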