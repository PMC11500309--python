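# Methods

This note records the model definitions, parameter choices, numerical
conventions, and known limitations of `patchyring`. Everything quantitative
here is computed by the test suite or by `scripts/acceptance.py`.

## Particles, targets, and geometry

A particle is a bead of van der Waals diameter σ = 2 Å carrying two patch
axes (unit vectors from the bead center to the patch centers). The angle
between a particle's two axes is fixed to the interior angle of the target
polygon, (n−2)π/n = 2.356, 2.513, 2.658 rad for n = 8, 10, 13. The
reference ring places beads on a circle at the bead–bead Lennard-Jones
minimum spacing 2^(1/6)σ, so the target is a local energy minimum and the
stability clock (T_stable) is well defined from step 0. Ring radius at
that spacing is 2.93 / 3.63 / 4.69 Å for n = 8 / 10 / 13, inside the
published cubic cells of 8 / 9 / 15 Å. Wall clearance is enforced on bead
*centers* at σ/4; a σ/2 clearance would be geometrically impossible for
the 10-ring in its 9 Å cell (3.63 + 1.0 > 4.5).

States: n = 8 and 10 alternate α/β around the ring (only unlike states
attract). For n = 13 the twelve non-γ particles form an alternating α/β
path and γ — attractive to both — bridges the path's two ends (one α, one
β neighbour). This is forced by parity: a 13-cycle with a 6/6/1 split and
attractive adjacencies everywhere admits no other arrangement. MD and the
100-particle system use a single state (all patches attract).

## Interactions

MC: truncated (unshifted) 12-6 LJ bead, ε_bead = 0.75 kJ/mol, r_c = 5 Å,
plus the Kern–Frenkel patch well: depth ε_patch on σ ≤ r < σ + δ gated by
r̂_ij·n̂_i ≥ cos θ^max on both sides (boundary inclusive), θ^max = 0.35
rad. δ = 0.9 Å is the largest round value satisfying the single-bond
inequality sin θ^max ≤ (σ/2)/(σ+δ) (0.3429 ≤ 0.3448); the inequality
guarantees geometrically that a patch can never hold two bonds, which the
suite verifies on 10⁵ random three-particle geometries.

MD: Jover's cut-and-shifted Mie (λ_r = 50, λ_a = 49) pseudo-hard-sphere
bead with ε_r = 0.24 kJ/mol (zero at (50/49)σ ≈ 2.041 Å, continuous
there), and the continuous square well between patch *sites* (at σ/2
along each axis): −(ε/2)[1 − tanh((r − r_w)/η)], r_w = 0.12σ = 0.24 Å,
η = 0.005σ = 0.01 Å. The square-wave drive adds ±A to the well depth
(high phase first, 50 % duty, period 20 ps, zero time average); the low
phase may make the effective depth negative (transiently repulsive
patches) — no clamping.

## Monte Carlo engine

Single-particle moves: translation uniform in ±max_translation per axis,
or rigid rotation of the patch frame about a uniform random axis by a
uniform angle in ±max_rotation; both proposal densities are symmetric.
Reflective walls reject any proposal placing a bead center outside the box
(equivalent stationary measure to reflection for symmetric proposals);
periodic runs wrap coordinates and use minimum-image distances.

Move sizes are not physical parameters; they set the MC clock. Defaults
max_translation = 1.0 Å, max_rotation = 0.4 rad give ~33 % equilibrium
acceptance at 65 K (mid-plateau coupling), in the middle of the 30–50 %
calibration band and close to the classic one-third-acceptance efficiency
heuristic. **One reported "MC step" is one sweep** — n attempted
single-particle moves — the common convention for system-size-comparable
step counts; `MCParams.sweep_definition="move"` switches to raw proposals.

The drive classifies each proposal by its effect on target-adjacent
bonds. A bond is `bond_indicator = 1`: well range and both gates open for
an attractive state pair. Adjacency mode `state-compatible` (default)
counts any such bond — with alternating rings, any unlike-state bond
extends to a target labeling; `labeled` restricts to the exact target
quadruples. Moves that both form and break n_f/n_b bonds get a net bias
(n_f − n_b)·ε_drive in the exponent, which reduces to the three-case rule
(forming / breaking / persisting-neutral) when a single flip occurs.

Bookkeeping: a pair-energy cache makes each proposal one O(n) scan; the
cached total energy is compared with a full recomputation every 10⁵ moves
and the run aborts if they differ by more than 10⁻⁸ kJ/mol (the suite
exercises this check). Bond partner arrays rely on the single-bond
guarantee and are revalidated at the same checkpoints. The first R = 1
and first R < 1 events are detected exactly at the move where they occur,
independent of the recording stride.

## Entropy production

S is the standard stochastic-thermodynamics trajectory functional for a
Markov chain with symmetric proposals: each accepted move contributes
ln[a(x→x′)/a(x′→x)], the log-ratio of forward and reverse acceptance
probabilities, which evaluates to −(ΔU − bias)/k_BT with bias =
(n_f − n_b)·ε_drive. Rejected moves contribute nothing. At equilibrium
the sum telescopes to −ΔU_total/k_BT — identically zero around closed
loops, fluctuating with zero long-run rate — while the drive's
forming/breaking asymmetry produces a positive mean rate during assembly
that saturates once all bonds persist (the bias stops acting). The suite
asserts the telescoping identity exactly and the rate contrast
numerically.

## MD engine

Each particle is one rigid body: bead (10 amu) at the body origin, two
patch sites (1 amu) at σ/2 along the body-frame axes. The site masses
supply the full inertia tensor (principal moments 2 sin²(φ/2),
2 cos²(φ/2), 2 amu Å² for interior angle φ); the bead at the origin
contributes nothing. Treating the bead center as the center of mass
ignores the small site-mass offset — a deliberate simplification of the
reduced-fidelity engine. Site forces map to a body force plus torque.

Integration: velocity Verlet at dt = 0.2 fs; orientations propagate by
exact quaternion rotation for the half-step body angular velocity, with
the Euler (ω × Iω) term evaluated explicitly — reversible to < 10⁻⁶ Å
over 100 NVE steps at this dt, and energy-conserving to < 0.1 % of the
well depth over 10⁴ NVE steps (both tested). A single Nosé–Hoover
thermostat couples to the total (translational + rotational) kinetic
energy with damping time 0.1 ps (unpublished; exposed in `MDParams`);
Q = g·k_BT·τ², g = 6N − 3. The extended conserved quantity is tracked and
reported. Pair forces are clamped at 10⁴ kJ/mol/Å to survive pathological
overlaps in random initializations.

Bond criterion in MD: patch-site distance < r_w + 2η (the smooth well has
no sharp edge; the threshold sits at the well shoulder and is exposed in
`MDParams.bond_scale`). Bond events are detected at the recording stride
(100 fs) and tagged with the drive phase.

## Protocols and metrics

T_fas: first time R = 1 from a random start; runs that never assemble
enter the ensemble median at the simulation cap (censoring convention).
T_stable: first time R < 1 from a target start, same convention. The
departure criterion is the strictest reading (any single broken target
bond); a persistence window is available in the analysis layer.
T_enhance = median T_fas(equilibrium)/median T_fas(driven) — values > 1
mean the drive accelerates assembly. (The opposite verbal convention
would make the reported ~35-fold improvements read as 1/35; the
fold-improvement reading is the consistent one.)

Region segmentation of a median-vs-ε_patch curve: Region I = leading
couplings with medians at ≥ 95 % of the cap; Region III = trailing
couplings, after the global minimum, whose medians exceed 1.5× the
provisional plateau (threshold exposed); Region II = the rest, its mean
median being the reported plateau.

## Scaled-down problem sizes

Published ensembles are 20 realizations per condition with 10⁷-sweep caps
(15 × 10⁶ for n = 13). The packaged reproductions run desk-scale versions:
`scripts/acceptance.py` uses 8–12 realizations per coupling for the 8-
and 10-particle plateaus (three couplings each: 10/20/30 and 10/14/18
kJ/mol), 6 realizations at each of two plateau couplings (9 and 10
kJ/mol) for the 13-particle system — the third, strongest example
coupling is dropped as the costliest, since it censors most realizations
at the 15 × 10⁶-sweep cap — and 5 equilibrium + 10 driven realizations
for the enhancement ratio. The acceptance-test suite runs 6-seed
versions. Medians over 6–12 seeded realizations carry sampling error
comparable to the ±50 % spread of the published per-realization scatter;
the 13-particle median in particular sits near the upper edge of that
band here, because nearly half of its realizations are censored at the
cap under this engine's MC clock.

## Known limitations

- Absolute MC-step scales depend on unpublished move sizes and the sweep
  definition; they are calibrated only through the acceptance-rate band
  and the sweep convention above. Relative structure (plateau ordering,
  drive convergence to the plateau) is the robust content.
- The MD engine is reduced-fidelity: no long 12 000 ps × 20-replicate
  sweeps, bead center treated as center of mass, global drive phase for
  all bodies, thermostat constants unpublished. MD claims are validated
  through short-run signatures (two-particle bond events and force
  fluctuations, deep-well ring stability), not through full T_fas/T_stable
  sweeps.
- Bond lifetimes under a strong drive (amplitude > baseline depth) are
  measured across net-repulsive low phases, where shoulder-crossing
  flicker shortens apparent lifetimes; the durability trend is therefore
  tested at weak coupling from random starts, where both arms produce
  events.
- The synthetic ensembles emulate the published study conditions
  (temperatures, box sizes, coupling grids, censoring); they do not model
  experimental colloids — hydrodynamics, polydispersity, and solvent
  effects are out of scope.

## What the enhancement factor can and cannot reproduce

Under a strong drive at weak coupling (ε_patch = 3, ε_drive = 7) this
engine's median first-assembly time converges to its own equilibrium
Region II plateau — the drive removes the Region I bottleneck but does not
beat the optimal equilibrium kinetics. T_enhance therefore takes the value
cap/plateau (≈ 10 here with the 10⁷-sweep cap), and that ratio structure,
not the absolute fold value, is the reproducible content: the absolute
fold depends on the MC clock through the plateau, while the censoring cap
in the numerator is protocol-fixed. `scripts/acceptance.py` reports the
honestly computed ratio of medians.
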