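"""Charged nanoparticles redistribute over the potential map.

A fixed number of cationic particles in Boltzmann equilibrium with the
cell potentials distributes with density proportional to
exp(-z V/V_T): the particles concentrate around hyperpolarized cells.
Here they are allocated over the cross-patterned map from the blocker
example.
"""

import numpy as np

import bioelectric as be

model = be.default_model()
lattice = be.LatticeSpec(50, 50)
_, depol = be.stable_levels(model, 1.0)
initial = be.make_initial_condition(lattice, "uniform", depol)
cross = be.make_2d_profile(lattice, 0.05, 2.5)
final = be.simulate(
    initial, be.couple_to_ensemble(cross, lattice), model, be.CouplingParams(g=0.25),
    be.SimConfig(t_hat_final=60.0, steady_state_tol=1e-8),
).final

potentials = final.potentials_mv(model)
spec = be.NanoparticleSpec(total_count=10000, valence=1.0)
table = be.allocation_table(potentials, spec, model.thermal_potential)
counts = table["count"].to_numpy().reshape(50, 50)

mid = lattice.rows // 2
unstable_mv = be.find_fixed_points(model)[1].potential
depolarized = potentials > unstable_mv
print(f"total particles allocated: {table['count'].sum()} (exactly the requested {spec.total_count})")
print(f"mean count on the hyperpolarized cross arm   : {counts[mid, :].mean():6.2f} per cell")
print(f"mean count on depolarized cells (the corners): {counts[depolarized].mean():6.2f} per cell")
v_lo, v_hi = potentials[mid, 0], potentials[0, 0]
print(f"(Boltzmann factor between those potentials: exp(({v_hi:.1f} - {v_lo:.1f})/27) "
      f"= {np.exp((v_hi - v_lo) / 27):.1f}x)")

out = be.render_heatmap(final.grid, "scratch_particle_map.png", model, particle_counts=counts)
print(f"wrote overlay heatmap to {out}")
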