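"""Normalization of a depolarized patch by gap-junction coupling.

A 50x50 lattice of hyperpolarized cells contains a 10x10 central patch
of depolarized cells.  With strong junction coupling (g = G/G_in =
0.25) the normal neighborhood acts as an electrical buffer and reverts
the patch; with weak coupling (g = 0.05) the patch is electrically
isolated and its core is still depolarized after one second (t_hat =
10, since tau = C_0/G_in = 0.1 s).
"""

import bioelectric as be

model = be.default_model()
lattice = be.LatticeSpec(50, 50)
levels = be.stable_levels(model, 1.0)
initial = be.make_initial_condition(lattice, "central_patch", levels, patch_shape=(10, 10))
fields = be.CellFields.uniform(lattice, 1.0)

for g in (0.05, 0.25):
    traj = be.simulate(
        initial, fields, model, be.CouplingParams(g=g),
        be.SimConfig(snapshot_times=(0.0, 5.0, 10.0)),
    )
    print(f"\ng = {g}:")
    for snap in traj.snapshots:
        s = be.summarize(snap, model, fields)
        print(
            f"  t_hat = {snap.t_hat:5.1f} (t = {snap.t_hat * model.tau_seconds:.2f} s)  "
            f"depolarized fraction = {s['fraction_depolarized']:.4f}  "
            f"mean V = {s['mean_potential_mv']:.1f} mV"
        )

print("\nThe depolarized fraction starts at 100/2500 = 0.04 in both runs;")
print("strong coupling drives it toward zero, weak coupling leaves the core depolarized.")
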