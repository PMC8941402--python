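# Methods

## Model

Each filiform hair is a rigid rod of nondimensional length L̃_h in a
linear torsional socket (spring constant S̃_h), hinged at its base on
the plane and carrying its whole charge q̃_h at the tip.  Motion is
planar; the deflection angle θ_h is measured clockwise from vertical
(+y) toward +x, so the tip sits at
(x̃_{h,0} + L̃_h sin θ_h, ỹ_{h,0} + L̃_h cos θ_h).  In the quasi-static
regime — inertial and damping torques neglected, appropriate for fixed
or slowly moving charges — the elastic torque balances the tangential
component of the Coulomb forces from the other hairs' tip charges and
from an external point charge at each instant:

    θ_h − θ_{h,0} = K (q̃_h L̃_h / S̃_h)
                    [ q̃_p T_h(p) + Σ_{i≠h} q̃_i T_h(i) ],
    T_h(s) = ((x̃_h − x̃_s) cos θ_h − (ỹ_h − ỹ_s) sin θ_h) / r̃_{hs}³.

Lengths are in units of the typical hair length L, springs of the
typical S, charges of the typical q; the single surviving group
K = q²k_e/(LS) (Coulomb constant k_e = 8.988e9 N m² C⁻², kept at the
commonly quoted rounding so derived numbers match published worked
values) measures electrical relative to mechanical torques.  The point
charge is immobile: hairs do not move it.

The residual of the balance equals (1/S̃_h) ∂U/∂θ_h for the total energy

    U = Σ_h ½ S̃_h (θ_h − θ_{h,0})² + K Σ_{h<i} q̃_h q̃_i / r̃_{hi}
        + K q̃_p Σ_h q̃_h / r̃_{hp},

which the test suite uses as an independent stationarity oracle
(central finite differences, step 1e-6, gradient ≤ 1e-6 at every
converged equilibrium).

### Assumptions and their limits

* Planar geometry (z ≡ 0), hairs diameterless; the hair diameter enters
  only the surface-charge bound q = π d L σ.
* All charge at the tip; other distributions (dipole, uniform) rescale
  the response but change coupling quantitatively.
* Linear socket; results are threshold-independent as long as θ_s stays
  small, hence the configuration-level restriction θ_s ∈ (0, 0.1] rad.
* Single external point charge; no superposition of sources, no motion.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| K | electromechanical sensitivity, dimensionless | 1 | mid-range of the feasible span 0.001–100 derived from allometry and charge bounds |
| θ_s | sensory threshold, rad | 1e-3 (≈0.057°) | within the neurally effective deflection range reported for crickets and spiders |
| δ | hair spacing, hair lengths | — | biologically 0.03–0.1; studied over 0.01–10 |
| q̃_p | point-charge magnitude, units of hair charge | 10 in metric sweeps, 1–4 in contour fixtures | within an order of magnitude of the hair charge; acts as a pure range scaling (√q̃_p) |
| k_e | Coulomb constant | 8.988e9 | fixed; not configurable |
| σ | surface charge density, C m⁻² | 1e-4 | dielectric-breakdown limit |

Allometric relations (SI, L in meters): spring S = 1.272e-5·L^2.030
(spider MeD1) and 1.944e-6·L^1.67 (cricket cercal); diameter
d = 6.343e-5·L^0.3063 and 8.34e-4·L^0.67.  Both spring laws give
S = O(1e-11) at L = 1 mm, both diameters O(1e-6) — the orders on which
the feasible K range rests.  Note the surface-charge bound evaluates to
≈2.4e-12 C with these numbers, one order below the O(1e-11) sometimes
quoted alongside it; the calculator returns the formula's value.

## Numerics

**Equilibrium solver.** Damped Newton on the residual with an analytic
Jacobian, vectorized over batches of scenarios (each grid cell of a
deflection field is one scenario); backtracking halves the step until
the residual max-norm decreases.  Initialization at the resting angles;
on failure, geometric continuation in K (11 stages from K/1024), then
in spacing (9 stages from 10× spread).  This selects the solution
branch continuously connected to the resting configuration.
Convergence: residual max-norm ≤ 1e-10, ≤ 200 steps per stage.
Angles are capped at |θ| < π/2 during iteration; converged states are
flagged invalid if any |θ| ≥ π/2 or any tip pair is closer than 1e-3
hair lengths (near-singular geometry produces non-physical artefacts).
Tip or charge separations below 1e-9 raise a singular-geometry error.

**Asymptotics.** The small-angle formula (hairs on a near-flat
substrate) is explicit; its error is O(θ²L̃/δ) because it drops the tip
displacement, so it matches the full solver to 1e-6 rad for θ ≤ 1e-3
and δ ≥ 10, with quadratic contraction beyond.  The zero-spacing system
(coincident bases; inter-tip distances depend only on lengths and angle
differences) is solved by a hybrid root-finder seeded with a fan of
angles ordered by base position; for two identical hairs the fan
amplitude comes from the scalar closed form 4θ sin²θ = (q̃²/S̃L̃) K cos θ,
bracketed on (0, π/2) to 1e-12.

**Deflection fields.** Candidate charge locations are gridded
(default 401×401) over a box of half-width 1.5·√(K q̃_max |q̃_p|/θ_s)
centred on the base centroid — the far-field square law
|Δθ| ≈ K q̃ q̃_p / r² guarantees this contains the threshold contour.
All cells are solved in one batched Newton pass seeded from the
charge-free equilibrium; failures are retried from the nearest
converged neighbour, then masked.  Cells within 1e-3 hair lengths of a
tip are masked up front and never interpolated over.

**Contours.** Marching squares (scikit-image) at levels ±θ_s per hair,
masked cells set to NaN so level sets never cross them.  Branches ending
on the domain boundary are flagged `clipped`; branches cut by interior
masked zones are not (they close around the exclusion).  A warning fires
when the narrowest lobe spans < 3 cells.  On global grids the cell size
is of order one hair length, so near-hair contour detail is
under-resolved; consumers that need vertex-accurate values (the κ
profile) re-solve at each vertex and drop vertices whose solved
deflection strays outside [0.8, 1.25]·θ_s.

**Areas.** Midpoint cell counting on the membership field
(|Δθ_h| ≥ θ_s, masked cells excluded), robust to clipped and degenerate
regions; a shapely polygon union of closed branches provides a
cross-check (agreement ~0.1% on the single-hair reference).  Exact
point queries (`region_membership`) always use fresh solves, never grid
interpolation, and serve as the oracle: Monte-Carlo membership sampling
reproduces the gridded single-hair area to 0.2%.

**κ profile.** Contour points are binned by sensory direction — the
angle between the charge and the base centroid, from vertical, in
[−π/2, π/2]; 73 bins (2.5°).  θ_c is the re-solved coupled deflection
at the vertex, θ_uc a fresh solve of the hair isolated and *rested at
its coupled equilibrium angle* (so κ isolates coupling from
orientation).  Per bin: mean per hair, then minimum over hairs; empty
bins are NaN.

**Localization.** Nonlinear least squares (scipy `trf`) over (x, y)
and optionally q̃_p, with the observation Jacobian obtained by implicit
differentiation through the equilibrium solve
(dθ/dp = −J⁻¹ ∂F/∂p).  32 multi-starts by default, on four rings whose
radii bracket the far-field distance implied by the observed deflection
magnitudes; ring phases are seeded for reproducibility.  Local minima
with RMS misfit ≤ max(max_residual, 1e-8) are deduplicated at 1e-4 hair
lengths and returned sorted; `max_residual` (default 1e-6) must be
raised for noisy observations.  The two-hair ambiguity locus intersects
the two iso-deflection curves per trial magnitude, preferring the
upper-half-plane intersection at the first magnitude (the sensing side
of the substrate) and continuity thereafter.

## Design choices where the design was open

* **Solution multiplicity is reported, not suppressed**: symmetric
  arrays produce mirror candidate pairs and 3-hair unknown-magnitude
  problems can admit more than one exact solution; all are returned
  with a multiplicity count.
* **Problem sizes**: test and sweep grids use 201–401 points per axis;
  the area metrics change ≤ 0.2% under doubling at the reference
  settings (K=1, δ=1, q̃_p=10), so these resolutions are converged for
  the metrics reported.  The localization recovery suite runs 50
  scenarios at 8 ring starts, which recovers all noiseless cases.
* **Binning for κ** (73 bins) and the centroid definition of "middle of
  the array" are conventions; results are insensitive to both at the
  resolutions used.

## What the fixtures emulate — and what they do not

The named fixtures (`figure1d`, `figure3_cell`, `figure5_panel`,
`random_array`) generate idealized rows of hairs with order-unity
nondimensional parameters on a flat substrate: the canonical
two-hair configurations of the underlying model study.  Real arrays
differ in ways the model deliberately omits: curved substrates and 3-D
geometry, hair-diameter mechanics and viscous (aerodynamic) hair–hair
coupling, distributed (non-tip) charge, time-varying stimuli and
neural transduction.  Passing tests therefore validate the
electrostatic-coupling model and its numerics, not a full account of
any particular species' sensory performance.

## Known limitations

* Strong coupling at tiny spacing (K = 100, δ ≤ 0.1) produces
  near-singular tip geometry; such states are flagged invalid rather
  than trusted.
* Global deflection grids under-resolve near-hair contour structure
  (cells ~ one hair length); all quantitative consumers either mask or
  re-solve there, but exported contour CSVs retain the raw vertices.
* The equilibrium branch is the one continuously connected to rest;
  no stability classification beyond energy stationarity, and no
  search for disconnected equilibria.
* Localization assumes the observation pattern is reachable by a
  single point charge; inconsistent observations return an empty
  candidate list.
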