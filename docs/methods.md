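# Methods

## Model

The simulator treats brain tissue as a saturated poroelastic medium with
four fluid networks — arterioles, capillaries, venules and the
interstitial space — superposed on an isotropic linear-elastic skeleton.

**Steady perfusion.** In the intact brain, interstitial exchange is
negligible, so the blood phase alone is solved in steady state: three
Darcy equations coupled by inter-compartment transfer terms
`ω_ac (p_a − p_c)` and `ω_cv (p_c − p_v)`. Blood enters and leaves only
through the cortical (pial) surface: the arteriole pressure is prescribed
there (ABP), the venule pressure likewise, the capillary bed carries no
boundary flux, and the ventricle surface is impermeable to blood. An
arterial occlusion zeroes the arteriole boundary flux over the occluded
territory while the remaining cortex stays at ABP. The tissue-feeding
perfusion measure is the capillary→venule transfer `ω_cv (p_c − p_v)`; a
cell belongs to the ischaemic (oedema) core when this rate, evaluated at
the cell midpoint, falls by at least 70 % relative to the healthy solve.
The 70 % threshold is the standard clinical criterion for severely
hypoperfused tissue; it is a configuration key.

Arterioles and venules are penetrating vessels, so their permeability is
transversely isotropic with principal axis perpendicular to the pial
surface; on the idealized geometry that axis is radial. The transverse-to-
axial ratio defaults to 0.01 (only the scalar magnitudes are constrained
by the literature; the strong anisotropy expresses that penetrating
vessels conduct poorly sideways, and it is what localises the perfusion
deficit under the occluded territory). An isotropic mode exists and is
used by the oracle tests.

**Oedema.** With the barrier damaged and perfusion restored, plasma
filters into the interstitium at the Starling rate

    S_cw = (2 n_b L_p / R_c) [ (p_c − p_w) − σ Π_c ],

active only in the frozen core (the healthy barrier leaks ~100× less, so
leakage outside the core is neglected; no damage-evolution law is
modelled). The four pressure equations march with backward Euler; the
exchange and Starling terms are treated implicitly, which is
unconditionally stable since the coupled system stays linear in the
pressures. The system matrix is constant over the run, so one LU
factorisation serves all steps. `S_cw` is allowed to go negative
(reabsorption) late in a run; a `clamp_starling` switch suppresses that if
wanted.

**Mechanics.** Deformation equilibrates on seconds while oedema grows
over many minutes, so inertia and the displacement rate are dropped and a
quasi-static equilibrium `div σ_eff = ∇p_w` (σ_eff = 2G ε + λ tr ε I) is
solved after each pressure step. λ is the first Lamé parameter computed
from (G, ν); ν = 0.35 and G = 592.7 Pa by default. The pial surface is
fixed (the membranes tethering the brain to the skull are far stiffer
than parenchyma); the ventricle surface is free of effective traction
except for contact. Kinematics are small-strain on the undeformed mesh
even at several millimetres of midline shift — "large deformation" enters
the problem through ventricle collapse, which is geometric (contact), not
constitutive.

**Ventricle self-contact.** The thin ventricle slits close when swelling
exceeds their width. Non-penetration of the opposing walls is enforced
with a node-to-surface augmented-Lagrangian scheme: slave-wall nodes are
projected onto the deformed master wall (closest-point, ties to the
lower facet index), the penetration `g > 0` generates a normal traction
`⟨λ_N + ε_N g⟩`, and the multiplier is updated between augmentations,
`λ_N ← ⟨λ_N + ε_N g⟩`, until the re-detected penetration falls below
`g_tol`. Implementation details that proved necessary for robustness:

- each augmentation solves its frozen-pairing problem *exactly* by
  active-set (semismooth Newton) iteration, using the Woodbury identity
  against the prefactored elasticity matrix (the contact term is low
  rank);
- master-wall normals are facet normals averaged to the wall nodes, so
  the gap function is continuous when a projection slides across a facet
  junction;
- the iterate that drives re-pairing and the multiplier update is
  under-relaxed (factor 0.5): frictionless parallel walls have a neutral
  tangential mode whose re-pairing otherwise limit-cycles;
- displacement is warm-started across time steps, keeping each
  augmentation a small correction.

Defaults: `ε_N = 10 G/h`, `g_tol` = 1 % of the slit thickness,
augmentation cap 120; all are configuration keys. Contact is frictionless
and normal-only, and there is no skull contact (the pial surface is fixed
anyway).

## Synthetic geometry

The built-in domain is a 2D plane-strain disc of radius 80 mm standing in
for a bihemispheric axial section: all governing equations are
dimension-agnostic, and the 2D domain exposes every algorithm (occlusion,
core extraction, transient leakage, collapse, contact, fits) at desk
scale. Its features, all configurable:

- **Ventricle slits**: two vertical cavities at x = ±10 mm, 3 mm wide,
  spanning y ∈ [−50, 10] mm. The posterior offset mirrors the posterior
  extension of the lateral ventricles (body plus occipital horn). The
  3 mm width puts collapse inside the simulated ICP range.
- **Interhemispheric fissure notches**: narrow cuts along the midline
  from the anterior pole down to y = 25 mm and from the posterior pole up
  to y = −40 mm. Their surfaces are pial (hence mechanically fixed),
  anchoring the midline at the poles the way the longitudinal fissure and
  falx do in vivo; only the central corridor at ventricle level can
  shift. Without them a posterior (PCA-like) core pushes the free
  posterior midline directly and the oedema-type slope ordering loses the
  near-zero PCA slope seen clinically. The falx as a distinct elastic
  structure is *not* modelled.
- **Territories**: angular sectors per hemisphere — anterior 60°
  (ACA-like), lateral 90° (MCA-like), posterior 30° (PCA-like) — sized so
  core volumes order MCA > ACA > PCA. The fissure walls are tagged ACA
  anteriorly and PCA posteriorly (medial cortical surfaces). This is a
  surrogate of a vascular atlas, not an anatomical claim.
- **Meshing**: the right half-plane is point-sampled on an h-grid with
  feature lines snapped to shared coordinates, Delaunay-triangulated,
  Laplacian-smoothed in the interior, re-triangulated, and mirrored
  through x = 0 — so the mesh is *exactly* symmetric and the midplane
  node column sits exactly on x = 0. Default h = 2 mm. A slit narrower
  than h, or shorter than 3h, is rejected as under-resolved.

What the synthetic geometry does **not** emulate: real cortical folding,
3D ventricular shape, the falx as a membrane, gray/white heterogeneity,
and any patient-specific registration. Passing tests therefore establish
the correctness and qualitative structure of the model, not quantitative
agreement with imaging-derived anatomy; slopes and volumes are on the 2D
surrogate's own scale (2D "volumes" assume 1 mm out-of-plane depth).

## Parameters

Defaults (all configurable, YAML-overridable, SI after parsing):

| symbol | meaning | default |
|---|---|---|
| K_a, K_c, K_v | blood permeabilities | 1.234, 4.28e-3, 2.468 mm³·s/kg |
| ω_ac, ω_cv | transfer coefficients | 1.326e-6, 4.641e-6 /(Pa·s) |
| p_a, p_v at cortex | boundary pressures | 12000 Pa (90 mmHg), 2000 Pa (15 mmHg) |
| c_w, c_b | storage factors | 3.08e-4, 1.59e-3 /Pa |
| K_w | interstitial permeability | 3.6e-3 mm³·s/kg |
| L_p | capillary-wall hydraulic permeability | 3.0e-11 m/(s·Pa) |
| σ, Π_c | reflection coeff., plasma osmotic pressure | 0.65, 2445 Pa |
| n_b, R_c | blood volume fraction, capillary radius | 0.03, 5e-6 m |
| G, ν | shear modulus, Poisson ratio | 592.7 Pa, 0.35 |
| p_w boundary | CSF pressure (baseline ICP) | 10 mmHg |

1 mmHg = 133.322 Pa; the constant is configurable so rounded literature
values (12000 Pa = 90 mmHg) can be reproduced exactly. `L_p` is the
blood-brain-barrier severity dial; σ is a plain input (no estimation
procedure is implemented).

## Protocols

- **Schedule**: 1000 s total, Δt = 125 s (8 recorded post-initial
  states). Initial blood pressures come from the healthy steady solve at
  the scheduled ABP; p_w starts at the 10 mmHg baseline, making the
  healthy state an exact fixed point when L_p = 0.
- **ABP sweeps**: the venule boundary tracks ABP − 75 mmHg exactly (fixed
  arteriovenous offset). Default sweep 80–100 mmHg: beyond ~105 mmHg the
  plane-strain surrogate swells so far that the slit region folds
  geometrically; the chosen range already spans ICP ≈ 13–26 mmHg.
- **Slope fitting**: MLS vs (ICP − baseline) through the origin (MLS is
  zero without a pressure rise); R² is reported for the constrained fit
  (1 − SS_res/Σy²). L_p and oedema-type comparisons fit each case's own
  time series at ABP 90.
- **Confidence ellipse**: Gaussian ellipse from the sample mean and
  covariance of pooled (ABP, ICP) samples at the 75 % level
  (semi-axes √(χ²₂(0.75)·eigenvalues)), plus an ordinary least-squares
  line.

## Numerics

P1 (piecewise-linear) triangles for all fields; per-cell constant
coefficients. Dirichlet data imposed strongly by row elimination.
Boundary fluxes are recovered from the unconstrained discrete residual
(conservative evaluation), which makes the steady arteriole/venule flux
balance and the per-step interstitial storage/flux/source audit close to
linear-solver precision — the audits in the test suite guard the
assembly, not the algebra. Linear systems are solved by sparse LU
(SuperLU) with factorisation reuse: the problems are desk-scale
(≈5–20 k unknowns), where a direct method is both faster and more robust
than the Krylov/AMG stack a cluster-scale run would use. Displacement and
midline shift are reported in mm, pressures in Pa (mmHg at the reporting
surface).

Degenerate inputs are rejected with explicit messages: under-resolved
slits, fully-occluded cortex (singular arteriole block), non-positive
healthy perfusion (ill-defined relative reduction), empty midplane sets,
probe points outside the domain, inverted cells flagged in volume-change
output.

## Verification structure

Every numerical kernel is checked against an independent reference that
shares no assembly code: the capillary balance against 0-D algebra (the
whole-domain-Dirichlet `pin_blood` variant is exactly the 0-D problem),
the transient interstitial solver against the Fourier series for a slab
(itself cross-checked against implicit finite differences), the
elasticity solver against a radial two-point boundary-value integration
on an annulus plus exact homogeneous patch tests, and the contact update
against the closed-form bar-against-stop problem. Structural properties
(fixed point at L_p = 0, mirror symmetry, linearity in the ABP increment,
slope saturation in L_p, oedema-type slope ordering) run on the full
pipeline.

## Known limitations

- 2D plane strain; quantitative slopes/volumes are surrogate-scale.
- Small-strain kinematics at large midline shift; volume-change output
  reports both the exact geometric and small-strain measures so the
  discrepancy is visible.
- Frozen core, no damage evolution, no osmotherapy or haemorrhagic
  transformation, no CSF circulation, no autoregulation, no large-vessel
  network.
- The fissure notches anchor the midline but the falx is not a modelled
  structure; pial fixation everywhere overstates tethering at extreme
  ICP.
- Stress summaries use von Mises of the effective stress with a 5 mm
  periventricular band and exclude a 5 mm pial boundary layer from the
  "intraparenchymal" maximum (fixed-boundary corners concentrate stress
  artefactually); both the band and the exclusion are analysis choices.
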