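"""The bistable resting potential of a two-channel model cell.

Builds the reference cell (inward rectifier pinning -60 mV, outward
rectifier favoring 0 mV) and finds the zeros of the total current: two
stable resting potentials separated by an unstable threshold.  The
lowest stable root is the normal hyperpolarized state; the highest is
the abnormal depolarized state associated with plastic/cancer-like
cells.
"""

import bioelectric as be

model = be.default_model()
print("channel pair:")
print(f"  inward : G = {model.inward.conductance} nS, E = {model.inward.equilibrium_potential} mV")
print(f"  outward: G = {model.outward.conductance} nS, E = {model.outward.equilibrium_potential} mV")
print(f"  V_th = {model.inward.threshold} mV, z = {model.inward.gating_charge}, V_T = {model.thermal_potential} mV")

print("\nresting potentials (zeros of the total current):")
for fp in be.find_fixed_points(model):
    print(f"  V* = {fp.potential:8.3f} mV  [{fp.stability}]")

print("\nA cell sitting below the unstable root relaxes to the")
print("hyperpolarized state, above it to the depolarized state:")
print("the pair acts as a two-state bioelectric memory.")

# hysteresis in E_in at equal conductances
res = be.bifurcation_diagram(model, [x * 0.5 - 90 for x in range(120)], [1.0])
window = res.branch(1.0).query("n_roots == 3")["e_in"]
print(f"\nbistable E_in window at G_out/G_in = 1: [{window.min():.1f}, {window.max():.1f}] mV")
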