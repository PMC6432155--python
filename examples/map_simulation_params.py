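"""Map bead-spring simulation parameters onto the phase diagram.

For each bending potential the ratio k2 is a constant (bending and folding
derive from the same potential), so varying K_theta moves a simulation
vertically through the diagram along a fixed k2 column.  The harmonic rows
K_theta = 7.5, 15, 30 give k1 = 3.23, 6.46, 12.92.
"""

from polycollapse import BendingPotential, classify_state, map_sim_params, persistence_length

for kind in ("cosine", "harmonic", "stiff"):
    print(f"{kind} potential:")
    for ktheta in (7.5, 15.0, 30.0):
        m = map_sim_params(BendingPotential(kind, ktheta), epsilon=1.0, sigma=1.0)
        p = classify_state(m.k1, m.k2, L_star=600.0)
        print(f"  Ktheta={ktheta:5.1f}: k1={m.k1:6.2f} k2={m.k2:5.3f} -> {p.label}")

lp = persistence_length(BendingPotential("harmonic", 1.5), T_star=1.0)
print(f"persistence length at Ktheta=1.5, T*=1: lp/sigma = {lp:.2f}")
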