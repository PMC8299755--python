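# Methods

## Physical model

The modeled domain is the aortic annulus — the landing zone of a
self-expanding transcatheter prosthesis — idealized as a thick-walled
circular cylindrical shell.  Tissue is homogeneous, isotropic and linearly
elastic (small-strain Hooke's law).  Because the native leaflets are pressed
into the root wall after deployment, the shell carries a single homogenized
material: each property is the convex combination of the leaflet and root
rows of the shipped material table (root: E = 2 MPa, ν = 0.45,
ρ = 2000 kg/m³; leaflet: E = 8 MPa, ν = 0.45, ρ = 1100 kg/m³), weighted by
the patient's root volume fraction `P_root`.

Deployment is kinematically controlled at the wall surface: every
inner-surface node is displaced radially outward by the frame oversize
`max(0, R − C_annu/2π)` plus the local remodeled calcium thickness `d(φ)`,
with tangential and axial components clamped (the frame grips the wall).
Nodes inside the vacancy sector `(−θ/2, +θ/2)` — the cylindrical sector
removed from the frame over the conduction zone — carry no prescription.
The scalar loading force `F = K (R − C_annu/2π + d)` summarizes the same
interference fit through the radial wall stiffness `K`; it is the bridge
between force and size in the inverse design, not a separate load path.
`R` is the device *radius* (nominal size / 2), since it is differenced
against the annulus radius `C_annu/2π`; nominal sizes are diameters.

### Calcium remodeling

Deposits are slabs of thickness `d` (regular) or two-endpoint rods
(irregular).  Remodeling translates each deposit along the radial line
through its center until the outer face touches the wall
(center radius = a − d/2), conserving volume, length and thickness exactly.
Irregular deposits then rotate rigidly about their displaced centroid, about
the axis perpendicular to both the rod axis and the radial direction; the
angle minimizes the larger endpoint-to-wall distance (coarse 0.25° scan plus
bounded refinement; the smallest-magnitude angle wins ties).  Deposits may
overlap after remodeling; the boundary condition sees only the per-sector
**maximum** thickness — a stack compressed by a rigid frame cannot protrude
beyond its thickest member.

### Discretization

Structured, circumferentially periodic hex8 mesh with trilinear shape
functions and 2×2×2 Gauss quadrature; the default resolution
(n_circ, n_axial, n_radial) = (92, 17, 5) gives the 7,820-element annulus
model the package ships.  Node ordering is φ-major, then axial, then radial,
so feature vectors align across patients at a fixed resolution.  Stress is
evaluated at quadrature points, averaged per element, then averaged to nodes
(simple recovery).  Rigid modes are removed by clamping axial displacement
on the two end faces; a `"full"` axial constraint option enforces
plane-strain kinematics for verification runs.  The solver is a direct
sparse LU (`MMD_AT_PLUS_A` ordering) on the reduced system; factorizations
are cached per constraint pattern so sweeps over sizes at fixed θ re-solve
only the right-hand side.  Verification: under uniform inner-surface
displacement the recovered hoop stress matches the plane-strain thick-walled
cylinder (Lamé) solution to better than 2% at the default resolution, and
the error does not grow under refinement.

### Conduction-zone features

The conduction-system zone is the interleaflet triangle between the
non-coronary and right-coronary cusps: a 90° sector centered on the NCC–RCC
commissure midpoint (the shared 0° reference), intersected with an axial
band of 4 mm above the annulus plane (the bundle's penetration depth; the
source anatomy gives no height, so this is a package choice).  The feature
vector is the von Mises stress at every inner-surface node in this zone, in
deterministic node order.  The AV-bundle radius (0.6 mm) is carried as a
configuration constant; the generator's risk summary weights zone nodes by
tributary area.

## Risk model

Features: stress block, total calcified volume V, and encoded clinical
factors (sex, BMI, pressures, LVEF, four binary comorbidities, plus two
derived location/distribution encodings: the fraction of calcified volume
inside the conduction sector, and the Shannon entropy of the volume-weighted
angular placement over 12 sectors).  Training always uses the complete frame
(θ = 0) at the applied device size.

The DX score `|μ₁ − μ₀| / (s₁ + s₀)` (class-mean separation over pooled
spread, sample standard deviations, ties broken by feature index) ranks
features; the top 16 are retained, and the cumulative impact percentage is
the selected share of the total score mass.  Selected features are z-scored
with training-fold statistics only.  The regression is a linear
ε-insensitive SVR, objective `λ‖w‖² + mean ε-loss` — i.e. libsvm cost
`C = 1/(2λn)`, the per-sample convention that keeps λ comparable across
cohort sizes — solved to tolerance 1e-6.  Defaults: ε = 0.01, λ by an inner
seeded 5-fold CV over the grid {1e-3 … 1e2}.  Predicted risk is the affine
score clipped to [0, 1]; AVB is called strictly above τ = 0.5, the only
threshold consistent with the reference behavior of the reported
per-patient risk table.

## Inverse design

The optimal design minimizes `|target_risk − g(σ(size, θ), V, …)|` with
target risk 0 (no AVB) by exhaustive enumeration over the 4 nominal sizes ×
θ ∈ {0, 1, …, 15}°.  The source form of this problem is ambiguous about
what the norm's first argument is; reading it as the valve size would be
circular (size is an output of the force law), so the target-risk reading is
used.  Ties — which occur systematically when the predicted risk clips to 0,
i.e. for patients whose conduction zone is already unloaded — resolve to the
smallest θ (prefer an unmodified frame), then the size closest to 1.15×
annulus diameter (conventional oversize).  θ_max = 15° covers the 0–12°
range observed clinically and is configurable.  Because vacant nodes are
unloaded, enlarging θ never increases conduction-zone stress, so for
positive stress weights the unclipped risk is monotone in θ; a vacancy is
recommended only when the predicted risk is strictly positive.

## Synthetic cohort

The generator emulates the study population the pipeline targets: n = 48
with 28 male / 20 female by deterministic quota; age ~ truncated normal
(79, 4) on [71, 88] years; BMI ~ (29.3, 4.5) on [21.3, 42.5] kg/m²; blood
pressures and LVEF from conventional clinical ranges (no reported values
exist for them); binary comorbidities at prevalence 0.3.  Annulus diameter ~
(24, 2) mm on [20, 28]; wall thickness uniform 1.5–2.5 mm; wall stiffness
K = 10 N/mm (a documented placeholder for the regression-derived constant);
the applied device is the nominal size nearest 1.15× the annulus diameter.
Annulus height is fixed at 10 mm so the conduction-zone feature count is
constant across a cohort.  Each patient carries 2–6 deposits; thickness ~
truncated normal (3.2, 1.2) mm on (0.5, 6.8] (the sd is chosen so the
reported maximum is plausibly reached at a few hundred deposits); total
calcified volume uniform on 318–683 mm³, split by a symmetric Dirichlet;
30% of deposits are irregular rods.  NCC/RCC deposits are placed within
±60° of the commissure and LCC deposits outside — encoding the clinical
observation that NCC/RCC calcium drives conduction injury while LCC calcium
loads the wall away from the bundle.

Labels come from a linear score on the area-weighted mean conduction-zone
stress (computed with the same forward physics at a coarse labeling
resolution (16, 3, 1), complete frame, applied size), calcified volume, sex,
BMI, diabetes and atrial fibrillation, passed through a logistic link with
temperature `noise_scale` (default 0.25; 0 makes the label the score sign,
with the boundary resolving to no-AVB).  The stress normalization constants
(center 1.25 MPa, scale 0.3 MPa) were calibrated once against the
generator's own stress-summary distribution.  Class balance is enforced by
quota on the noisy latent score (20/48 positive, proportional otherwise),
which reproduces the reported split exactly while preserving the label's
monotone dependence on the score.

What the generator does *not* emulate: imaging noise and segmentation error,
non-cylindrical annulus shapes, inter-patient conduction anatomy variation,
hyperelastic/anisotropic tissue behavior, and any real-cohort feature
correlations beyond those induced by the shared physics.  Passing tests
therefore demonstrate internal consistency and estimator correctness under
the stated generative model, not clinical performance.

## Sensitivity analysis

Each factor is perturbed multiplicatively by 25 seeded uniform draws over
[1 − r, 1 + r] (default r = 0.05); a factor's variation is the maximum
absolute change of predicted risk across draws and patients, relative to the
cohort-mean baseline risk.  Factor linkages are force-held throughout,
because a self-expanding frame is a force-delivering device: the loading
force scales the stress block proportionally (linear structure); Young's
modulus has zero first-order effect at fixed delivered force (σ = E·ε with
ε ∝ F/E); Poisson's ratio is re-solved and rescaled to the baseline total
radial contact reaction, leaving only stress redistribution (one-sided
linearization); tributary areas do not enter the fitted predictor (exact
zero); calcified volume and the fitted coefficients are perturbed directly.
Zero range gives exactly zero variation.  On the default synthetic cohort
the material factors (E, ν) are less influential than the biomechanical ones
(F, V), matching the expected ordering; the absolute variation of the
loading-force factor is large (tens of percent), because multiplying a
factor that drives *all* stress features compounds their mean-to-spread
ratios — the model is stable under perturbation of any single coefficient
(≤ ~2%) but genuinely sensitive to a coherent force error.

## Evaluation protocol

Leave-one-out CV refits the entire chain (DX selection, normalization, SVR,
optional inner λ-CV) inside every fold; folds whose training labels cannot
support selection fall back to all features with a warning.  ROC curves and
AUC (trapezoidal) are computed from the risk scores pooled over folds.
Baselines (logistic regression, depth-3 decision tree, one-hidden-layer
16-unit MLP, fixed seeds) see the same features and per-fold preprocessing.
The ablation compares stress-only, clinical-only (calcified volume +
clinical factors), and combined regimes.  A permutation guard checks that
risk scores shuffled against labels give AUC 0.5.

## Problem sizes used by the shipped tests

Unit and acceptance tests run the forward physics at the labeling resolution
(16, 3, 1) — where the conduction zone holds 6 feature nodes — except for
the solver-verification and mesh tests, which use the default 7,820-element
mesh.  Parameter recovery uses a 400-patient cohort at label noise 0.05 and
compares the fitted direction with the generator's gradient mapped into the
normalized feature space (cosine ≥ 0.9).  The acceptance script runs the
sensitivity analysis at the full default resolution.

## Known limitations

* Linear kinematics: oversize displacements of several millimetres imply
  finite strains that a small-strain model only approximates.
* No contact mechanics, friction, deposit fracture, or residual prestress;
  the vacancy sector's structural feasibility is not checked.
* The conduction-zone band height (4 mm) and wall stiffness default
  (10 N/mm) are package choices where the source anatomy is silent.
* The DX score formula is a standard signal-to-noise form; the cited
  selection method's exact formula is not public.
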