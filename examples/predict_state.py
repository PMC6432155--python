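"""Predict the collapsed state of a chain from its energy ratios.

A chain of dimensionless length L* = 600 is scored at three points of the
(k1, k2) plane: k1 = gamma_e/gamma_s (fold vs surface energy) and
k2 = gamma_b/(gamma_e sigma^3) (bending vs fold energy).  Low k1 gives a
compact globule; past k1 = 1 the chain elongates into a bundle; when
bending is cheap relative to folding (small k2) the torus wins.
"""

from polycollapse import classify_state

for k1, k2 in ((0.5, 1.0), (10.0, 5.0), (10.0, 0.5)):
    p = classify_state(k1, k2, L_star=600.0)
    print(f"k1={k1:5.2f} k2={k2:5.2f} -> {p.label:3s}  "
          f"G_torus={p.G_torus:8.2f}  G_bundle={p.G_bundle:8.2f}  "
          f"margin={p.coexistence_margin:.3f}")
    if p.label == "T":
        g = p.torus_geom
        print(f"    torus geometry: r_t={g.r_t:.3f}, R={g.R:.3f}, "
              f"aspect R/r={g.aspect_ratio:.2f} (constrained={g.constrained})")
    elif p.label in ("B", "G"):
        g = p.bundle_geom
        print(f"    bundle geometry: r_b={g.r_b:.3f}, l={g.l:.3f}, "
              f"aspect l/r={g.aspect_ratio:.2f}")

# free energies are in units of gamma_s sigma^2; the winning state is the
# lower of the two, with a 5% band flagged as fluctuating (T&B)
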