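# patchyring

Dissipative self-assembly of patchy particles under nonequilibrium drive:
a Monte Carlo and molecular-dynamics toolkit for ring-forming systems.

## The problem

Spherical colloids decorated with two attractive surface patches ("patchy
particles") can self-assemble into closed rings — the minimal model for
biological ring structures such as the 13-protofilament microtubule
cross-section. At equilibrium such assembly faces a trade-off: weak patch
attraction never assembles the target, strong attraction kinetically traps
the system in malformed aggregates, and only a narrow intermediate window
assembles reliably. Biology escapes this trade-off by spending energy (GTP,
ATP); this package implements the computational analogue — an external
drive that continuously biases bond formation — and the observables needed
to quantify what the energy buys.

`patchyring` targets rings of n = 8, 10, and 13 particles (with a 100-
particle periodic validation system) and is aimed at researchers studying
nonequilibrium self-assembly design principles.

## Models

**Monte Carlo (Kern–Frenkel).** Each particle is a Lennard-Jones bead
(ε_bead = 0.75 kJ/mol, σ = 2 Å, r_c = 5 Å) with two patches at the
polygon interior angle (n−2)π/n. A patch pair contributes a square well of
depth ε_patch when σ ≤ r_ij < σ + δ **and** both patches point along the
center line within θ^max = 0.35 rad:

U_patch = −ε_patch · [r̂_ij·n̂_i ≥ cos θ^max] · [r̂_ji·n̂_j ≥ cos θ^max],

with δ = 0.9 Å chosen so sin θ^max ≤ (σ/2)/(σ+δ) — each patch can hold at
most one bond. States α/β (plus γ for n = 13) make only unlike pairs
attractive. Sampling is single-particle Metropolis at 65 K with reflective
walls. The nonequilibrium drive ε_drive modifies acceptance for moves that
change target-adjacent bonds:

- forming: min[1, exp(−(ΔU − ε_drive)/k_BT)]
- breaking: min[1, exp(−(ΔU + ε_drive)/k_BT)]
- otherwise: plain Metropolis.

**Molecular dynamics (reduced fidelity).** Rigid bodies (10 amu bead + two
1 amu patch sites at σ/2), pseudo-hard-sphere bead repulsion (cut-and-
shifted Mie 50–49, ε_r = 0.24 kJ/mol), continuous square-well patch-site
attraction −(ε/2)[1 − tanh((r − r_w)/η)] with r_w = 0.12σ, η = 0.005σ.
Velocity-Verlet integration (dt = 0.2 fs) with quaternion rotation and a
Nosé–Hoover thermostat at 40 K, periodic boundaries. The MD drive is a
square wave U_square(t) of period 20 ps added to the patch well depth.

**Observables.** Order parameter R = (formed bonds)/(target bonds);
trajectory entropy production S = Σ ln[a_fwd/a_rev] over accepted moves
(k_B units); first-assembly time T_fas (first R = 1, censored at the run
cap); stability time T_stable (first R < 1 from a target start); and
T_enhance = median T_fas(equilibrium) / median T_fas(driven).

## Worked example

Build the 8-ring target and run one equilibrium realization at
ε_patch = 10 kJ/mol from a random start:

```
$ patchyring make-target --n 8
n=8 interior_angle=2.3562 rad bonds=8 box=8.0 A

$ patchyring run-mc --n 8 --epsilon-patch 10 --steps 2000000 --seed 7 --out run.csv
final R=1.000 T_fas=208955 wrote run.csv
```

This realization reached the fully bonded ring (R = 1) after ~0.21 × 10⁶
MC sweeps (one sweep = one attempted move per particle); `run.csv` holds
the R, S, and total-energy series. The same library calls are available in
Python:

```python
import patchyring as pr
from patchyring.mc import run_mc, MCParams, DriveSpec

box = pr.SimulationBox.cubic(8.0)
ref, target = pr.make_ring_target(8, box)
init = pr.random_configuration(8, box, seed=7)
ip = pr.InteractionParams().with_depth(10.0, 2)
series, state = run_mc(init, target, MCParams(n_steps=2_000_000, seed=7), ip)
print(pr.first_assembly_time(series, 2_000_000))
```

Driven runs pass `DriveSpec(eps_drive)`; MD runs go through
`patchyring.md.run_md` or `patchyring run-md`. Ensembles over
(ε_patch, ε_drive) grids use `patchyring sweep` and
`patchyring.experiments.run_sweep`, with region segmentation
(`segment_regions`) to locate the no-assembly / optimal / trapped regimes.

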