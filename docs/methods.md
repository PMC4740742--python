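# Methods

## Single-cell model

The cell is an equivalent circuit: a membrane capacitance `C_0` in parallel
with two voltage-gated conductances. Each channel carries
`I = G·p(V)·(V − E)` with a Boltzmann open probability

- inward rectifier: `p(V) = 1/(1 + exp[ z (V − V_th)/V_T ])` — open at
  hyperpolarized potentials, so it clamps the resting potential near its
  reversal `E_in`;
- outward rectifier: the mirror image (`−z`), favoring `E_out`.

Currents are positive outward and the isolated cell obeys
`C_0 dV/dt = −I_total(V)`, so a zero of `I_total` with **positive** slope
`dI/dV` is stable. This orientation of the gating exponent (inward channel
open as `V → −∞`) is what makes the inward rectifier the guardian of the
hyperpolarized state; with the reference parameters it produces exactly
three zeros, verified against a brute-force 0.01 mV sign-change scan:
−58.599 (stable), −15.537 (unstable), −7.536 mV (stable).

Parameters, with defaults and units:

| parameter | default | meaning |
|---|---|---|
| `G_in`, `G_out` | 1 nS | maximum channel conductances; their ratio is the main biological dial (upregulation raises it, blocking lowers it) |
| `E_in`, `E_out` | −60, 0 mV | channel reversal potentials, held constant (buffered ionic concentrations on electrical time scales) |
| `V_th` | −25 mV | half-activation potential, `p(V_th) = 1/2` |
| `z` | 3 | effective gating charge; sets sigmoid steepness |
| `V_T` | 27 mV | thermal potential `RT/F` at 310 K, stored as the literal constant so printed conversions (54 mV ↔ 2, 54 pA ↔ 2) are exact; `thermal_potential(T)` computes `RT/F` for arbitrary `T` (26.71 mV at 310 K, rounding to 27) |
| `C_0` | 100 pF | reference capacitance; `τ = C_0/G_ref = 0.1 s`, so `t̂ = 10` is 1 s |

Nondimensionalization uses `v = V/V_T`, `î = I/(G_ref V_T)`, `t̂ = t/τ` with
`G_ref = G_in` by default.

Root finding brackets sign changes on a uniform scan grid (default 0.1 mV,
required ≤ 1 mV) and refines with Brent's method to 1e-9 mV; stability uses
the analytic slope. A tangential (degenerate) root appears once with a
warning. The bifurcation sweep re-solves the zero-current equation over an
`E_in` grid for each conductance ratio and reports fold (saddle-node)
boundaries as the midpoints of consecutive `E_in` values where the root
count changes — resolution is therefore the `E_in` grid spacing, by design:
the diagram is validated structurally (existence and edges of the bistable
window), not against curve coordinates.

## Lattice ensemble

Cells sit on a rows×cols square lattice with 4-neighbor (von Neumann)
edges; boundary cells simply have fewer neighbors, the no-flux choice for a
finite tissue patch. Gap junctions are per-edge conductances
`g = G/G_ref` (uniform scalar or per-edge arrays); the junction capacitance
field is accepted for fidelity to the circuit diagram but must be 0 — the
conductive term dominates for typical junction values, so the capacitive
coupling is omitted from the dynamics. The extracellular reference
potential is 0.

The dynamics `dv/dt̂ = −î(v) − L v` (L the weighted graph Laplacian) are
integrated with a constant-matrix IMEX split:

    A = I + Δt̂·L   (assembled and LU-factorized once per run)
    B = Δt̂·[ −î(v^n) − L v^n ]
    solve A·Δv = B,   v^{n+1} = v^n + Δv

Equivalently `(I + Δt̂ L) v^{n+1} = v^n − Δt̂ î(v^n)`: coupling implicit,
channels explicit. Properties relied on by the tests: `A` is symmetric
positive definite with eigenvalues ≥ 1 (the solve is unconditionally safe),
a uniform state on a single-cell fixed point is exactly stationary, pure
coupling conserves `Σv`, and the trajectory converges to an explicit-Euler
reference with observed order ≥ 1. Defaults `Δt̂ = 0.01`, `t̂_final = 10`;
at these settings a 50×50 run (2500 unknowns, 1000 sparse solves on one
factorization) takes well under a second, and all shipped scenarios and
tests run at that full 50×50 scale. An optional steady-state tolerance
(max |Δv|/Δt̂) allows early stopping with the stop time recorded.

Initial conditions set cells exactly to the stable roots of their local
single-cell model: uniform, a centered rectangular patch (default 10×10,
read from the figure-scale scenario and exposed in config), or an arbitrary
mask. Optional Gaussian jitter requires an explicit seeded generator.

A cell is classified *depolarized* when its potential exceeds its local
single-cell **unstable root** — the basin boundary of the isolated-cell
dynamics, the least arbitrary threshold available. Where the local model is
monostable (e.g. ratio → 0) the cell inherits its single root's side of the
midpoint between `E_in` and `E_out`, so the fraction is 0 or 1 there.

### Patch-reversal timing

Under the reference conditions (50×50, 10×10 patch, ratio 1.0) the
depolarized patch shrinks by front propagation. At `g = 0.25` the fraction
falls 0.04 → 0.0016 by `t̂ = 10` (four central cells at −14.2 mV, just
above the −15.54 mV basin threshold), reaches exactly 0 by `t̂ ≈ 10.5`, and
the uniform hyperpolarized steady state by `t̂ ≈ 34`; at `g = 0.05` the
60-cell core is still depolarized at `t̂ = 10` and only dissolves near
`t̂ ≈ 60`. The weak/strong contrast is therefore read at the one-second
horizon (`t̂ = 10`), and complete normalization is asserted at steady
state. These timings were cross-checked against an LSODA integration at
rtol 1e-8 and are step-size independent; they shift with the patch
geometry, which is known only at figure precision.

## Blocker microenvironment

Blocking is a fast local equilibrium: the outward conductance scales as
`G_out(c) = G_out⁰/(1 + K·c)`, i.e. ratio `r(c) = r0/(1 + K·c)`, strictly
decreasing from the *unblocked* ratio `r0` at `c = 0` toward 0 at full
blocking. Letting `r0` exceed 1 covers simultaneously upregulated and
blocked channels, which is how a single profile can span ratios 0.05–2.50.
Only the product `K·c` is meaningful, so steady profiles are specified
directly in ratio space: three axial families (linear, exponential,
logistic in `x`, steepness 4 by default) renormalized to hit the endpoint
ratios exactly at the first and last columns, and a 2-D "cross" profile
built from the larger of two exponential decays of concentration away from
the central row and column (decay length 0.25 of the half-width), mapped
through the blocking law and renormalized so the cross attains the minimum
ratio and the corners the maximum. The construction is even in both axes,
hence mirror-symmetric.

Optional transport is Fickian diffusion with no-flux boundaries, integrated
by forward-time centered-space with a hard stability guard
(`ndim·D·Δt/Δx² ≤ 1/2`); reflecting ghost cells make mass conservation
exact to machine precision and preserve the discrete maximum principle.
The scheme is verified against the cosine-series closed form for a step
initial condition (max error 2e-3 at 100 cells, shrinking ≈4× at 200 —
second order in space). The characteristic time `τ_d = L²/D` (1e4 s ≈ 3 h
at L = 1 mm, D = 1e-10 m²/s) is orders of magnitude slower than electrical
relaxation, which justifies the steady-profile assumption in the
patterning scenarios. Blocker mass limitation, advection and 3-D domains
are out of scope.

## Nanoparticles

Particle density over the map follows Boltzmann statistics in the cell
potential: normalized weights `w_i ∝ exp(−z_np V_i/V_T)`, computed with a
max-shift so they are overflow-safe and exactly gauge-invariant (adding a
constant to all potentials changes nothing). The "potential a particle
sees" is the cell's map value, not a spatially resolved field. Integer
counts use largest-remainder rounding — conservation is exact, each count
is within 1 of its real-valued quota, remainder ties break toward the lower
cell index. Defaults (10 000 particles, valence +1) are nominal: the
physically testable content is ratios and ordering, not absolute counts.
Particle feedback on the membrane potential is not modeled.

## What the scenarios do and do not show

The scenario registry drives everything from configuration alone, at the
reference scale (50×50, `t̂ ≤ 10` unless running to steady state), writing
text snapshots with full-precision values and provenance headers
(parameter hash, tool version) so reruns are byte-identical. These runs
demonstrate the *mechanisms* — electrical normalization, isolation by weak
coupling, invasion under upregulation, blocker patterning, particle
redistribution — under idealized conditions: identical cells, constant
reversal potentials, no pumps, no ionic-concentration dynamics, no tissue
growth, deterministic dynamics. Passing tests establish the internal
consistency and numerics of this idealization, not quantitative agreement
with any particular cell line.
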