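# neuroperc

Simulators for two complementary models of metastable cortical dynamics:

1. **Neuropercolation** — a threshold activation (bootstrap-percolation
   style) process on a torus lattice augmented with random long-range
   "axonal" edges, together with its mean-field theory.  The neuropil is
   abstracted as the N×N torus ℤ²_N (4-neighbor short edges) plus long
   edges placed independently between vertices at L1 distance *d* ≥ 2 with
   probability

   p_d = min(1, c / (N·d^α)),

   and the synchronous update χ_v(t+1) = 𝟙(Σ_{u∈N(v)} χ_u(t) ≥ k).  The
   annealed mean-field closure gives a 1-D density map
   F(ρ) = E_{J~Pois(λ)} P(Bin(4+J, ρ) ≥ k), whose interior unstable fixed
   point is the critical initial density p_c(λ, k) separating extinction
   from full activation; λ is the mean long degree per vertex.

2. **CAN (capillary-astrocyte-neuron) model** — Izhikevich spiking
   neurons (v, u) coupled to two metabolic pools, astrocyte glycogen g and
   mitochondrial ATP m.  Recent membrane activity drives g over a sliding
   window of length τ (gain κ); g converts to m with saturation; and m
   feeds back into excitability through the effective sensitivity
   b⁺(m) = ωb + βm.  For β = 0 metabolism cannot influence spiking; for
   β > 0 the closed loop produces higher firing rates and, in coupled
   populations, bistable high/low-synchrony states with hysteresis — the
   coexistence region of a cusp in the (forward gain κ, feedback gain β)
   plane.

On top of the simulators sit synchrony analysis (Kuramoto order parameter
R(t) from analytic-signal phases of smoothed spike trains, Schmitt-trigger
state labeling, dwell-time statistics), hysteresis sweeps with loop-area
and bistable-interval readouts, a cusp bistability scan, and a phase-cone
fitter for lattice phase fields (φ ≈ φ₀ + γ·‖x − apex‖).

Intended users: computational neuroscientists studying criticality,
metastability and energy constraints in cortical network models.

## Worked example

```python
import numpy as np
from neuroperc import *

# mean-field critical point for threshold k=3 with one long edge per vertex
model = MeanFieldModel(lam=1.0, k=3)
sol = fixed_points(model)
print("fixed points:", [(round(r, 4), s) for r, s in sol.fixed_points])
print("p_c(lambda=1, k=3) =", round(sol.p_c, 4))

# finite-size check: calibrate c so the mean long degree is 1 on a 32x32 torus
c = solve_c_for_lambda(32, 1.0)
est = monte_carlo_critical(32, LongEdgeModel(c=c), k=3, reps=12, seed=3)
print("MC estimate: %.3f  (95%% CI %.3f-%.3f)" % (est.estimate, est.ci_low, est.ci_high))

# CAN unit with feedback gain beta = 0.25
tr = simulate_unit(IzhikevichParams(beta=0.25), MetabolicParams(), T=2000, dt=0.1, i_fn=10.0)
print("rate = %.1f Hz, ISI CV = %.3f, ATP m = %.2f" % (
    tr.firing_rate(500), tr.isi_cv(500), tr.m[-1]))
```

prints

```
fixed points: [(0.0, 'stable'), (0.5233, 'unstable'), (1.0, 'stable')]
p_c(lambda=1, k=3) = 0.5233
MC estimate: 0.488  (95% CI 0.480-0.504)
rate = 45.3 Hz, ISI CV = 0.000, ATP m = 0.67
```

The mean-field map for (λ=1, k=3) has the extinct and fully active states
stable and a basin boundary at ρ ≈ 0.523: initial densities above it flow
to full activation, below it to extinction.  The quenched Monte-Carlo
estimate on a 32×32 lattice lands within 0.04 of the mean-field value.
The CAN unit fires perfectly regularly (ISI CV ≈ 0) at 45 Hz — roughly
twice the metabolism-free rate, because the ATP pool equilibrates at
m ≈ 2/3 and raises b⁺ from 0.20 to 0.37.

A command-line interface mirrors the library:

```sh
neuroperc perc phase-diagram --lambdas 0,0.5,1,2,4 --ks 2,3,4 --out runs/pd
neuroperc can cusp --kappa-grid 0,0.0005 --beta-grid 0,0.4 --out runs/cusp
neuroperc run --config my_experiment.json --seed 7 --out runs/x
```

Every run writes CSV outputs plus a `manifest.json` with the fully
materialized configuration, so results are reproducible bit-for-bit.

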