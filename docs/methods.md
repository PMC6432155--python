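# Methods

## Continuum free-energy model

The chain is a continuous tube of diameter σ and dimensionless length
L* = L/σ, carrying volume πL*σ³/4 that is conserved in every candidate
geometry. Three energy densities score a collapsed state: γs (solvent
exposure, per area), γe (end folds, per area) and γb (bending, per
curvature² per unit length). Only the ratios k1 = γe/γs,
k2 = γb/(γe σ³) and L* matter; free energies are reported in units of
γs σ².

**Torus.** A circular tube of cross-section radius rt* and centerline
radius R*, with R* eliminated through volume conservation
(2π²R*rt*² = πL*/4). Lateral surface plus bending `γb L/R²` gives

    Gt*(rt*) = (π/2)L*/rt* + 64π² kb rt*⁴/L*,   kb ≡ k1·k2,

strictly convex with minimum rt* = (L*²/(512π kb))^(1/5) and
Gt*min = (5π/8)L*/rt* (at the optimum the bending term is exactly ¼ of the
surface term). Two geometric constraints apply: non-self-intersection
R* ≥ 2rt*, enforced by projecting the optimum onto the boundary torus
rt* = (L*/16π)^(1/3) whenever it is violated (convexity makes the boundary
point the constrained minimizer); and minimum thickness rt* ≥ ½, which is
reported as a `thin` validity flag but not enforced — it only serves to
bound the admissible k1 range below. kb = 0 is degenerate (the surface
term alone has no interior minimum); the boundary torus is returned with a
`degenerate` flag so grid scans stay total.

**Bundle.** A cylinder of end-cap radius rb* and length l* = L*/(4rb*²):

    Gb*(rb*) = (π/2)L*/rb* + 2π(1+k1) rb*²,

minimized at rb* = ½(L*/(1+k1))^(1/3), Gb*min = (3π/4)L*/rb*, where the cap
term is exactly ½ the side term. The optimized bundle satisfies the
identity 2rb*/l* = 1/(1+k1).

**Globule.** Not a separate functional: a bundle whose diameter/length
ratio reaches ½ — i.e. any k1 ≤ 1 — is a globule. This makes the
globule–bundle boundary the horizontal line k1 = 1, independent of k2 and
L*.

**Torus–bundle boundary.** Equating the two minima (equivalently
rb*/rt* = 6/5, which the suite checks directly) gives

    k2 = α⁵ L*^(1/3) (8+8k1)^(5/3) / k1,   α = (6/5)(512π)^(-1/5),

i.e. k2 = (6/5)⁵/(16π)·L*^(1/3)(1+k1)^(5/3)/k1, with large-k1 asymptote
k2 = (6/5)⁵/(16π)·L*^(1/3) k1^(2/3). Substituting the boundary relation into
the torus constraints yields the admissible range
2π(5/6)³−1 ≈ 2.636 ≤ k1 ≤ (5/6)³L*−1 ≈ 0.5787L*−1. Below the lower limit a
boundary-projected torus (R* = 2rt*) can still beat the bundle, which
produces the horizontal portion of the torus–bundle boundary at small k2;
the classifier reproduces this because it always compares the
constraint-projected torus against the bundle.

**Classification.** For each (k1, k2, L*) the classifier compares the
optimized free energies. Points with k1 ≤ 1 are globules even if the torus
energy is lower (the model treats sub-unity k1 chains as effectively
flexible). States within a relative band |Gt−Gb|/min(Gt,Gb) < 0.05 are
labelled T&B; the band denominator is min() for symmetry, and the 5%
default reflects the scale of thermal fluctuation between near-degenerate
minima at T* ≈ 1. Random coil is deliberately not an output: its entropic
free energy is not modelled, so the diagram covers collapsed states only.
Closed forms are used throughout the library; bisection solvers exist only
as independent oracles in the tests and acceptance script.

The model ignores structure-scale fluctuations and discrete filament
packing, so it is meaningful for long chains (L* ≳ 100–300) at
dimensionless temperatures of order unity. The L*^(1/3) factor in the
boundary means diagrams at different L* differ in the torus–bundle curve
while sharing the k1 = 1 line.

## Parameter mapping

The bead-spring mapping assumes close packing in the condensed state: an
exposed bead loses 8 of ~12 contacts at ε/2 each, spread over its cross
section, giving γs = 16ε/(πσ²). Bending maps as γb = Kθσ (σ being the only
length scale available). The end fold is a generic three-bead hairpin with
all three angles deviating 120° from straight and exposed area 3σ²:
γe = 3·U_angle(2π/3)/(3σ²). Three bending potentials of the deviation
δ = π − θ are supported — harmonic ½Kθδ², cosine ½Kθ(1−cos δ), and a
"stiff" combination 8·harmonic − 14·cosine that matches the harmonic
curvature at δ = 0 but rises faster (the δ²/2 ≥ 1−cos δ inequality gives
cosine ≤ harmonic ≤ stiff on (0, π]). Because γb and γe both scale linearly
in Kθ, k2 is a per-potential constant: 9/(2π²) ≈ 0.456 (harmonic), 4/3
(cosine), and ≈ 0.142 (stiff); k1 grows linearly in Kθ, with harmonic
coefficient π³/72 ≈ 0.43064 ε⁻¹. These mapped constants are sensitive to
the assumed fold geometry and packing numbers; other conventions for the
fold area or contact count shift k2 by factors of order one without
changing the qualitative picture (each potential is one vertical column in
the diagram, ordered cosine > harmonic > stiff in k2).

Persistence length is computed from the discrete worm-like-chain relation
lp = −l0/ln⟨cos δ⟩ with ⟨cos δ⟩ the Boltzmann average over the sphere
(weight sin δ·e^(−U/T*), adaptive quadrature at 1e-10 relative tolerance).
It tends to Kθl0/T* for stiff chains and is reported as NaN in the floppy
limit where ⟨cos δ⟩ ≤ 0.

## Brownian-dynamics simulator

Reduced LJ units (m = σ = ε = kB = 1, τ = √(mσ²/ε)). The force field is a
pearl-necklace chain: harmonic bonds ½Kb(l−l0)² with Kb = 1000 ε/σ² and
l0 = σ (stiff enough that bond fluctuations stay ≪ σ at T* = 1 without
forcing a smaller time step), one of the three bending potentials above,
and LJ 12-6 pairs with cutoff 2.5σ, energy-shifted to zero at the cutoff.
A WCA variant (cutoff 2^(1/6)σ) provides the athermal control; its force is
continuous at the cutoff, which is also why the energy-conservation test
uses it. Directly bonded (1-2) pairs are excluded from the pair sum; 1-3
pairs interact, the standard pearl-necklace convention. A chain of N beads
carries L* = N (one bead per σ of contour; N−1 bonds).

The thermostat uses the damp-time convention: friction force −(m/damp)v,
default damp = 10τ, T* = 1, dt = 0.005τ. The default integrator is BAOAB
splitting of underdamped Langevin dynamics: it is stable with the stiff
bonds at dt = 0.005, reduces exactly to velocity Verlet when the thermostat
is off (damp=None, used by the NVE energy-conservation test), and gives
kinetic temperatures accurate to well under 1% in the thermostat test. A
position-only Euler–Maruyama integrator for the strongly overdamped limit
is available as a config switch; its effective mobility dt·damp/m makes it
appropriate for soft force fields or smaller time steps, and the default
therefore stays with BAOAB. Noise is pre-generated per thermo chunk from a
seeded PCG64 generator, so trajectories are bitwise reproducible for a
given seed. Blow-ups (non-finite coordinates or |x| > 10⁶σ) abort with the
offending step index.

Desk-scale validation replaces production-scale phase-boundary sweeps
(hundreds of beads × 10⁸ steps, far beyond a test suite): the suite runs
50-bead chains for up to 10⁶ steps — enough to verify fluctuation–
dissipation (⟨T⟩ = 1 within 5%), exact forces against central differences,
collapse of an attractive flexible chain below its athermal control
(3-seed medians), and a simulated persistence length within 15% of the
quadrature value. Those checks validate the machinery, not the simulated
location of the phase boundaries, which at these sizes would be dominated
by finite-size and kinetic effects.

## Shape classification and synthetic fixtures

Descriptors come from the gyration tensor: eigenvalues λ1 ≥ λ2 ≥ λ3
(rg² = λ1+λ2+λ3), asphericity, acylindricity, the minimum radial bead
distance from the λ3 axis ("hole radius"), and extents along the
eigenvectors. The rules are: globule when λ1/λ3 ≤ 3; torus when oblate
(λ1/λ2 ≤ 3 ≤ λ2/λ3) with hole radius > 1σ; bundle when prolate
(λ1/λ2 ≥ 3, λ2/λ3 ≤ 3) with axial/transverse extent ≥ 2; otherwise
unknown. All thresholds are fixed in one config block and justified solely
by label-recovery tests on synthetic fixtures (≥95% at 0.3σ noise, 100
seeds per kind); they are deliberate order-of-magnitude separations, not
fitted values. Torus aspect ratio is estimated as mean ring radius over RMS
spread about the ring; bundle aspect as axial extent over √2×RMS transverse
radius (the √2 makes the estimator exact for beads filling a uniform disc).
A trajectory is labelled T&B when, over its last third, both torus and
bundle frames occur and the minority label holds ≥ 20% of them — an
operationalization of a fluctuating two-state condensate.

The fixture generator produces idealized bead clouds: a constant-pitch
winding over the torus tube surface, parallel strands rastered through a
sunflower arrangement in the bundle cross-section, and a uniform ball for
the globule, each plus isotropic Gaussian noise. These emulate the bead
density and overall symmetry of condensed chains but not their
connectivity, local packing order, thermal breathing modes, or partial/
defective condensates (racquets, half-formed tori). Passing label-recovery
tests therefore demonstrates the classifier separates the three ideal
symmetry classes robustly under positional noise — not that it resolves
every marginal structure a long BD run can produce; borderline frames fall
back to `unknown` rather than guessing.

## Numerical choices and known limitations

* All file writers emit `%.10g`, making outputs diff-stable and round-trip
  lossless at 10 significant digits; diagram generation is fully
  deterministic.
* Grid scans label cells via the same scalar classifier used for single
  points (no separate vectorized path to drift out of sync).
* Free-energy comparisons near the boundary are exact closed-form
  evaluations, so the T&B band is symmetric and reproducible; ties at
  band = 0 resolve to the bundle.
* The theory-side aspect ratios reported for mapped simulation rows come
  from this package's optimized geometries (e.g. l*/r* = 8.46 at k1 = 3.23;
  the constrained R*/r* = 2 at k1 = 6.46). Published tabulations derived
  from other fold/packing conventions can differ by factors of order one,
  as discussed under the parameter mapping.
* Short chains (L* ≲ 100) violate the continuum assumptions (few windings/
  folds quantize the free energy); the model is reported as-is there, with
  the `thin`/`constrained`/`degenerate` flags marking where geometry left
  its domain of validity.
* The simulator is O(N²) per step with open boundaries and no hydrodynamic
  interactions; it is a validation tool for qualitative collapse behaviour,
  not a production engine.
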