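# helistent

Mechanics-based design of helical airway stents.

Children and adults with tracheobronchomalacia — a weak, collapsing
airway wall — can be supported either by positive-pressure ventilation
(typically 5–10 cmH₂O) or by an indwelling stent. A single-wire helical
stent is attractive because it leaves most of the mucosa uncovered,
resists migration like a screw, and can be removed by unscrewing it. The
design question is quantitative: how thick a wire and how tight a coil
are needed so the stent gives the airway the same support as
positive-pressure ventilation, while adding as little foreign material
as possible?

`helistent` answers that with a closed-form elastic rod model of the
helix and a small set of design tools built on it. It is a library plus
a CLI for engineers and researchers designing wire-coil airway (or
similar radially loaded) stents.

## Model

The stent is an inextensible elastic rod of round NiTi wire (diameter
*d*<sub>wire</sub>, modulus *E*, Poisson ratio *ν*), shape-set as a
helix of centreline diameter *d*₀ and pitch *p*₀. In the wire body frame
a helix of diameter *d* and pitch *p* has constant curvature/twist

&nbsp;&nbsp;**u**(d, p) = [0, 2π²d/c², 2πp/c²],&nbsp;&nbsp;c = √(π²d² + p²),

where *c* is the wire length of one coil. With section stiffnesses
*k*<sub>b</sub> = EI and *k*<sub>t</sub> = GJ, the stored energy of a
wire of total length *l* is

&nbsp;&nbsp;E = (l/2) (**u** − **û**)ᵀ K (**u** − **û**),&nbsp;&nbsp;K = diag(k_b, k_b, k_t).

Radial compression to a given *d* < *d*₀ keeps the central portion
helical; its pitch is the energy minimizer, the positive real root of a
quartic (the quadratic coefficient vanishes identically) solved via the
companion-matrix eigenvalue problem. Static equilibrium of the rod under
a frictionless distributed contact load then gives the radial line force
in closed form,

&nbsp;&nbsp;f = (u_y² + u_z²)/u_z · [(k_t − k_b) u_y u_z − k_t û_z u_y + k_b û_y u_z],

and a uniform transmural pressure ρ converts to line force by
f = ρ·πdp/c. Inverting ρ(d) (Newton–Raphson from d = d₀ with a
bisection fallback) yields the deformed diameter, pitch, and the stent
area ratio (d/d₀)² under any pressure.

On top of the single-case solver sit the design tools: a wire-diameter ×
helix-angle design table, the *maximum-pitch* criterion (pitch at which
the thin wire already loses 30 % of stent area at 10 cmH₂O), the
*minimum-pitch* criterion (largest pitch at which two candidate wires
differ by < 5 % in area ratio — below it the wire choice stops
mattering), and the deployment rule that picks the smallest available
stent diameter at or above the measured airway diameter so the stent
stays preloaded against the tissue.

## Worked example

The deployed-design case — 0.51 mm wire, 25° helix angle on a 12.7 mm
template, 10 cmH₂O:

```sh
helistent deform --wire-mm 0.51 --angle-deg 25 --template-mm 12.7 \
                 --coils 3 --pressure 10cmH2O
```

```json
{
  "result": {
    "area_ratio": 0.9400611084104225,
    "area_reduction_percent": 5.993889158957755,
    "diameter_mm": 12.807986479855574,
    "helix_angle_deg": 25.023422491267464,
    "line_force_N_per_m": 16.690917079551344,
    "outer_diameter_mm": 13.317986479855573,
    "pitch_mm": 18.783072926163566,
    "pressure_Pa": 980.6649999999973
  }
}
```

Reading: under 10 cmH₂O the 13.21 mm stent narrows to 12.81 mm and
lengthens (pitch 18.60 → 18.78 mm), keeping 94 % of its cross-sectional
area — the stent-only contribution; tissue bulging between coils is not
modelled. The full resolved configuration (including the defaulted
E = 75 GPa, ν = 0.3) is echoed in the report.

The design window for the 0.38/0.51 mm wire pair:

```sh
helistent criteria
```

reports `max_pitch_mm: 28.25` (35.3° helix angle: more pitch loses over
30 % of area) and `min_pitch_mm: 10.11` (14.2°: less pitch makes the
two wires indistinguishable to within 5 %). `helistent design-table`
and `helistent sweep` write the corresponding CSV tables, and
`helistent select --trachea-mm 13.2` picks 13.21 mm from the default
candidate set.

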