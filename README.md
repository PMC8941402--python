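# hairfield

Quasi-static electrostatic modelling of arrays of charged mechanosensory
hairs — the filiform hairs and trichobothria with which insects and
spiders sense weak electric fields.

## The problem

Arthropod filiform hairs are slender, deflectable mechanoreceptors,
mechanically an inverted pendulum in a torsionally sprung socket.  When
such hairs carry electric charge, an external point charge — and every
*neighbouring charged hair* — exerts Coulomb torques on them.  An array
of charged hairs is therefore an electrostatically *coupled* sensor:
each hair's deflection, and hence its sensitivity to external charges,
depends on its neighbours.

`hairfield` implements the quasi-static (inertia- and damping-free)
planar model of this system for biologists and biophysicists studying
arthropod electroreception:

* coupled nonlinear equilibria of N charged hairs, with closed forms for
  the small-angle and zero-spacing limits and an energy-stationarity
  oracle;
* **sensitivity contours** — the loci of point-charge positions that
  deflect a hair by exactly the sensory threshold θ_s;
* sensory-coverage metrics: total detection area, two-hair overlap
  ratio, left/right directional areas, and the coupling parameter
  κ = (θ_uc − θ_c)/θ_uc (negative κ: a neighbour *enhances* sensitivity);
* the inverse problem: localizing a point charge (position and
  magnitude) from observed hair deflections.

## Model

Hair h, with nondimensional base position (x̃_{h,0}, ỹ_{h,0}), length
L̃_h, charge q̃_h (at the tip) and spring constant S̃_h, deflects by the
angle θ_h (clockwise from vertical) satisfying

    θ_h − θ_{h,0} = K (q̃_h L̃_h / S̃_h) · [ q̃_p T_h(p) + Σ_{i≠h} q̃_i T_h(i) ]

where T_h(s) = ((x̃_h−x̃_s) cos θ_h − (ỹ_h−ỹ_s) sin θ_h)/r̃_{hs}³ is the
tangential Coulomb factor of source s at the tip of hair h, and

    K = q² k_e / (L S)

is the **electromechanical sensitivity**: the one dimensionless group
(charge² × Coulomb constant over hair length × spring stiffness) that
sets the strength of every electrostatic effect.  Biologically feasible
values span K ≈ 0.001 … 100 (from allometric spring-constant laws for
spider MeD1 trichobothria and cricket cercal hairs, and surface-charge
bounds).  Geometry is measured in hair lengths; the hair spacing δ and
the external charge magnitude q̃_p complete the parameter set.

## Worked example

```python
import numpy as np
from hairfield import (make_row_array, solve_equilibrium, deflection_field,
                       extract_contours, contour_extent, overlap_ratio)

# two identical unit hairs, one hair length apart, moderate coupling
cfg = make_row_array(2, delta=1.0, K=1.0)        # theta_s defaults to 1e-3 rad
eq = solve_equilibrium(cfg)
print(np.round(eq.angles, 6))        # [-0.339611  0.339611]

# where does a charge q_p = 10 deflect at least one hair by theta_s?
field = deflection_field(cfg, 10.0, nx=301, ny=301, equilibrium=eq)
contours = extract_contours(field, 1e-3)
print(np.round(contour_extent(contours[0]), 1))  # [188.2 133.3]

print(round(overlap_ratio(cfg, 10.0, nx=301, ny=301), 3))   # 0.698
```

The mutual repulsion splays the pair to ±0.3396 rad before any external
charge appears.  The left hair's threshold contour spans ~188 hair
lengths horizontally but only ~133 vertically — the elongated reach and
the reduced vertical range (the "blind spot" above a hair) are the
model's characteristic sensing footprint.  About 70% of the pair's total
detection area is covered by *both* hairs, the region where the pair
can in principle infer a charge's position and magnitude.

The same workflows are available from the shell:

```
hairfield fixtures --kind figure1d --out cfg.json
hairfield equilibrium --config cfg.json --out eq.csv
hairfield contour --config cfg.json --qp 10 --out contours.csv
hairfield sweep --K 0.1,1,10,100 --delta 0.01,0.1,1,10 --out sweep/
```

## Layout

| module | contents |
|---|---|
| `model_core` | domain types, nondimensionalization, allometric/charge calculators |
| `equilibrium` | coupled equilibrium solver, asymptotic closed forms, energy oracle |
| `deflection` | point-charge deflections and gridded deflection fields |
| `contours` | signed iso-deflection contour extraction, membership oracle |
| `metrics` | areas, overlap ratio, directional areas, κ profile |
| `localization` | least-squares charge localization, two-hair ambiguity locus |
| `io` / `sweep` / `cli` | config I/O, fixtures, (K, δ) sweep runner, `hairfield` CLI |
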