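# Methods

## Model and assumptions

The stent wire is a Kirchhoff/Cosserat rod: inextensible, unshearable,
linearly elastic, with diagonal section stiffness
K = diag(k_b, k_b, k_t), k_b = EI and k_t = GJ for the solid round
wire. The deformed stent is assumed to remain a uniform helix; this
holds for the central coils of a radially compressed helix, while the
end coils deviate. Stents are sized to overhang the supported airway
segment on both ends, so only the central helical region is modelled
and end effects are ignored.

Contact with the airway wall is frictionless and purely radial, and the
transmural pressure is uniform. Under these assumptions the pitch at a
prescribed diameter follows from energy minimization (a quartic
stationarity condition) and the supported pressure follows in closed
form from rod equilibrium; no discretization of the rod is involved.

The model covers radial *compression* only. Expansive (negative)
transmural pressure is rejected rather than extrapolated, because the
contact and sign conventions are derived for the compressive case.

Sign convention: the body frame has x pointing from the wire toward the
helix axis, so the contact line force on the wire is positive inward.
Public functions return the force and pressure magnitudes; the signed
quantity is used internally by the inverse solver, where its sign
change across d₀ usefully extends the residual to the upper bracket
edge.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| E | 75 | GPa | Effective linear modulus of the NiTi wire. Superelastic NiTi has no single modulus; 75 GPa is a typical austenite value. All forces and pressures scale linearly in E, so any other choice rescales the pressure axis exactly. |
| ν | 0.3 | — | Sets only the torsion/bending ratio k_t/k_b = 1/(1+ν). |
| template diameter | 12.7 | mm | Shape-setting mandrel; the reference for angle↔pitch conversion (p = π·d_template·tan θ) and the base of the helix diameter d₀ = template + d_wire. |
| wire diameters | 0.38, 0.51 | mm | Candidate set for the design sweep. |
| reference pressure | 10 | cmH₂O | Positive-pressure-ventilation-equivalent load for design evaluation. 1 cmH₂O = 98.0665 Pa exactly. |
| target area reduction | 0.30 | — | Defines the maximum-pitch criterion on the thin wire. |
| wire-insensitivity tolerance | 0.05 | — | Defines the minimum-pitch criterion on the wire pair. |
| coils | 3 | — | Affects total wire length and energy only; the per-unit-length equilibrium, and hence every diameter/pressure result, is independent of it. |

"Diameter" throughout is the wire-centreline helix diameter; the outer
diameter adds one wire diameter. Area ratio is (d/d₀)² on the
centreline diameter. Lumen-based definitions differ by O(d_wire/d₀)
and would shift criterion pitches slightly; the centreline is the
quantity the rod model actually tracks.

## Numerical choices

* **Pitch quartic.** Solved by `numpy.roots` (companion-matrix
  eigenvalues). Roots with relative imaginary part below 1e-9 are
  treated as real; among positive real roots the energy minimizer is
  selected, and energy ties below 1e-12 relative resolve to the root
  nearest the unloaded pitch (continuity of the deformation path).
* **Pressure inversion.** Newton–Raphson from d = d₀ with a central
  finite-difference derivative (step 1e-8·d₀, one-sided at the upper
  boundary); convergence at |Δd| < 1e-10 m, at most 100 iterations. If
  an iterate leaves (0.3·d₀, d₀] or the derivative degenerates, the
  solver falls back to Brent bisection on [d_lo, d₀], halving d_lo from
  0.5·d₀ until the residual changes sign. The ρ = 0 case returns the
  exact identity state (zero energy and force by construction, not by
  solving).
* **Criterion solvers.** Bracketed Brent bisection on pitch at 0.01 mm
  tolerance. Monotonicity of the criterion function is verified on a
  coarse scan before solving; non-monotonicity aborts with a diagnostic
  rather than returning an arbitrary root. The default bracket spans
  helix angles 5°–50° on the template: above ≈50° both candidate stents
  are deep in collapse and the wire-diameter area gap stops growing
  with pitch, so a wider bracket would defeat the monotonicity check
  without containing any additional physical solutions. If the
  insensitivity tolerance is met across the whole bracket, the upper
  edge is returned (every bracketed pitch qualifies).
* **Sweeps** assert at runtime that area ratio is non-increasing in
  pressure and abort otherwise, so a multivalued or non-converged
  inverse can never be silently tabulated.
* **Units.** All library computation is SI; the CLI converts mm,
  degrees and tagged pressure units at the boundary. Every formula is
  homogeneous, so consistent non-SI inputs give identical dimensionless
  outputs (tested to 1e-12).

## Verification strategy

Two independent oracles back the closed-form solvers in the test suite
and the acceptance script:

* the quartic pitch is checked against a dense-grid minimization of the
  energy quadratic form (1 µm grid, bounded scalar refinement inside
  one cell), agreeing to 1e-6 relative;
* the closed-form line force is checked against the virtual-work
  identity |f| = (2/l)·|dE_min/dd| evaluated by central finite
  difference, agreeing to 1e-3 relative.

Both oracles re-derive their quantity from the energy function alone
and never touch the code paths they validate. Further property tests
cover the inverse-map roundtrip (1e-8 relative), exact linearity of
pressure in the modulus, and the identity/monotonicity of the
pressure–diameter map.

Seeded random test geometries span wires 0.2–1.0 mm, helix angles
10°–40°, templates 8–20 mm, moduli 40–83 GPa and pressures up to
20 cmH₂O — the realistic airway-stent envelope. Everything the suite
exercises is synthetic and model-internal: passing tests show the
implementation solves the stated rod model correctly and reproduces the
published design arithmetic, not that the model matches any particular
animal or bench measurement.

## Known limitations

* **Tissue is out of scope.** The model predicts the stent-only area
  ratio. In a malacic airway the tissue between coils stretches inward
  and contributes most of the additional area loss at larger pitches;
  design decisions based on this package alone use the stent-only
  number.
* **Linear elasticity.** Superelastic NiTi shows a stress plateau; at
  the small strains of normal operation the linear model is reasonable,
  but the absolute pressure scale inherits the uncertainty of the
  effective modulus. Dimensionless conclusions (which wire/pitch pairs
  behave alike) are modulus-robust; absolute criterion pitches are not.
  With the default 75 GPa, the 30 %-reduction criterion lands at a
  35.3° helix angle and the 5 % wire-insensitivity criterion at 14.2°;
  both criterion pitches shift upward with a stiffer modulus (a
  monotonicity the design tests verify), so the window edges carry a
  modulus uncertainty of order a degree.
* No buckling, coil-on-coil contact, viscoelasticity, end-coil
  boundary effects, or temperature dependence.
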