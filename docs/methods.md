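# Methods

This note documents the model implemented in `mwablate`, its numerical
treatment, the default parameters and the reasoning behind the open
design choices. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Bioheat model

Temperature is governed by the Pennes equation on a regular voxel grid
(world coordinates in mm, thermal quantities in SI):

    rho C_p dT/dt = div(lambda grad T) + omega rho_b C_p_b (T_b - T) + Q_appl

Assumptions: homogeneous, isotropic, non-deforming tissue; perfusion
acts as a volumetric sink toward arterial temperature; no
electromagnetic field solution (the applicator is a prescribed
deposition profile); no tissue shrinkage, swelling or vascular
infarction inside the thermal model.

### Perfusion and the vessel heat sink

The distributed perfusion rate is damage-modulated,

    omega(x) = omega0 * g(Omega),   g(Omega) = exp(-Omega)
               (a step rule g = 1{Omega < 1} is available by config),

so perfusion ceases smoothly as coagulation accrues. On the segmented
vasculature the rate is *multiplied* by `vessel_enhancement`
(default 50), representing the lower flow resistance of vessels larger
than the capillary bed. Two points were genuinely open and are
resolved here as package choices:

- whether the vessel sink replaces or compounds the distributed term:
  we multiply the damage-modulated rate (`50 * omega0 * exp(-Omega)`),
  i.e. the enhancement rides on top of the distributed model;
- the exact temperature/damage dependence of perfusion: the
  exponential-in-damage rule is smooth, testable (its limit at large
  damage is zero) and captures the qualitative cessation behaviour.
  A consequence worth noting is that a heavily damaged vessel voxel
  stops cooling — a crude occlusion analogue — which makes the
  simulated heat-sink effect weaker than a constant-flow vessel model
  would be.

The sink can be disabled (`SolverConfig.vessel_sink_enabled=False`) to
replay the no-vascular-cooling configuration; the distributed
perfusion remains active in either case. Perfusion is restricted to
the liver mask when one is present.

### Evaporation and the enthalpy-form update

Water evaporation is folded into an effective heat capacity: a
rectangle model that spreads the latent heat
`w * L = 0.778 * 2.26e6 J/kg` uniformly over the band 99-100 degC.
The explicit scheme advances the *volumetric enthalpy*
`h = rho * e(T)` with `e' = C_p_eff` and inverts the piecewise-linear
enthalpy afterwards. This is algebraically identical to the
temperature update outside the band, but it cannot step across the
band without paying the latent heat, and it makes the insulated-box
energy balance exact to round-off (verified to ~1e-13 by the
acceptance script).

### Discretization and stability

7-point central differences on the uniform grid; Dirichlet ghost
voxels at the configured boundary temperature (default 37 degC, far
from the ablation) or mirror ghosts for the insulated test
configuration. Axes of length 1 carry no flux, so quasi-1D problems
run on degenerate grids. The explicit step enforces

    dt <= rho C_p,min / (2 lambda sum_i 1/h_i^2 + omega rho_b C_p_b)

voxelwise and raises rather than integrating unstably; the automatic
step is 0.9x the bound. A semi-implicit backward-Euler variant
(coefficients frozen per step, sparse direct solve) exists for
verification on small grids; explicit and implicit agree within
0.5 degC on a reference heating problem. Verification anchors: the
steady perfused slab matches the cosh/sinh closed form within 1% at
0.5 mm spacing with ~2nd-order grid convergence, and perfusion-only
relaxation matches the exact exponential ODE to 1e-6.

Each ablation is simulated on a sub-box around the active zone
(default margin 40 mm) with the far field held at 37 degC; the damage
field is embedded back into the full grid. Sequential ablations reset
the temperature (they are treated as independent), each ablation's
damage is thresholded separately, and the per-ablation masks are
united.

## Applicator source and calibration

The deposition is axisymmetric about the applicator axis: Gaussian
radial falloff (`radial_sigma_mm`, default 4.5 mm) around the active
zone segment (default length 14 mm), Gaussian axial taper beyond the
zone ends (`axial_taper_mm`, default 3 mm), normalized so the volume
integral equals `efficiency * power` (default efficiency 0.7) at
baseline temperature. Any axisymmetric two-parameter family able to
produce ellipsoidal ablations would serve; this one is declared in the
configuration. A sigmoid absorption factor decays from 1 to a floor of
0.2 across the evaporation band, standing in for the reduced microwave
absorption of desiccated tissue. Neither the efficiency nor the
absorption shape is observable directly; both are fit/config
quantities.

`calibrate_source` fits `(radial_sigma_mm, efficiency)` by
deterministic least squares on relative errors of simulated vs
tabulated ablation length and diameter over the table rows. The
forward model inside the fit measures ablation dimensions by
interpolating the log-damage field along rays (sub-voxel resolution);
voxel-counting extents would make the objective piecewise constant.
Tables with fewer than 4 rows raise (underdetermined); residuals above
25% raise with diagnostics. The self-consistency test (table generated
by the forward model with known parameters) recovers both parameters
to well under 1%.

The packaged manufacturer table is **synthetic**: generated by this
forward model in homogeneous tissue over 80/90/100 W and 3-10 min
(`scripts/make_default_table.py`), with dimensions spanning
37.5x31.5 mm to 49.7x45.3 mm — representative of a 100 W-class
applicator. Real vendor tables can be supplied as CSV
(`power_w, duration_min, length_mm, diameter_mm`); lookups are
bilinear with no extrapolation.

## Damage model

Arrhenius kinetics `dOmega/dt = A exp(-Ea/(R T_K))` with liver
literature defaults `A = 7.39e39 1/s`, `Ea = 2.577e5 J/mol`, threshold
`Omega = 1` (the 63.2% denaturation convention). All three are
configurable and echoed into every result manifest, since the
predicted extent is sensitive to them. With these constants the
baseline rate at 37 degC is ~2.9e-4 1/s, i.e. a 10-minute exposure at
body temperature accrues Omega ~ 0.18 — far below threshold but not
zero; this is a known property of low-activation-energy liver
parameter pairs, and it mildly depresses the distributed perfusion
through the shutdown rule over long ablations. Time-to-threshold at
constant temperature has the closed form `t = exp(Ea/(R T_K))/A`,
which the implementation reproduces to 1e-6, and damage accumulation
is exactly additive over sub-steps.

## Synthetic phantoms

The generator emulates the study conditions of a retrospective MWA
cohort:

- livers: voxelized ellipsoids, semi-axes drawn from
  (52-64) x (44-54) x (38-46) mm, on 2 mm isotropic grids (1 mm is the
  recommended clinical reconstruction; 2 mm keeps cohort replays in
  minutes and the metrics tests run at 1 mm);
- vessels: recursive symmetric bifurcation with Murray's-law radius
  decay (`r_parent^3 = sum r_child^3`), branch angles ~35 degrees
  jittered by seed, root radius 3 mm, clipped to the liver. Radii fall
  below the 1 mm relevance limit for cooling within a few
  generations, which motivates the default depth of 3-4. When a
  target vascular fraction is requested, the tree near the first
  applicator is iterated — a feeder branch crossing the manufacturer
  reference ellipsoid is bisected on its radius — until the metric is
  within +-1 percentage point; the background tree is kept out of the
  ellipsoid neighbourhood so the feeder alone controls the fraction.
- plans and settings: 1-6 ablations per case (weights 0.40/0.40/
  0.15/0.05 for 1/2/3/6, matching a cohort dominated by one or two
  overlapping ablations), powers {80, 90, 100} W with 80 W most
  frequent, durations 3-10 min, successive ablation centers 10-16 mm
  apart;
- vascular fractions: ~25% of cases above the 5% heat-sink-relevant
  threshold, uniform in (5, 22.2]%; the rest uniform in [0, 5)% —
  spanning the 0-22.2% range reported for such cohorts;
- ground truth: fabricated from a sink-*enabled* simulation, eroded
  within 3 mm of vessels (a fixture device emulating heat-sink
  indentation, not a physical claim; depth configurable);
- artifacts, applied to the ground truth only: an infarction wedge —
  a cone from a surface apex to the nearest liver-capsule point
  (12 degrees half-angle), flagging the case `gt_overestimated` — at
  rate 0.15, and rigid misalignment (6 mm translation, ~5 degree
  rotation, nearest-neighbour resampling) at rate 0.10, emulating
  registration error.

What the phantoms do **not** emulate: CT intensities and contrast
phases, real vascular topology, deformable registration error,
segmentation noise, or the physics of vascular occlusion. Passing
cohort tests therefore demonstrates internal consistency of the
pipeline and the qualitative heat-sink signature, not clinical
accuracy.

## Metrics conventions

- Surfaces are voxel point sets (mask minus its 6-connected erosion);
  no marching-cubes meshing, which suffices at 1-2 mm spacing.
- Signed distance: for each predicted-surface voxel, the Euclidean
  distance to the nearest ground-truth surface voxel, positive where
  the voxel lies outside the ground truth (ground truth enclosed),
  negative inside. The "nearest surface point" reading was chosen
  over a ray-casting interpretation, which is ambiguous for concave
  shapes; both the AAE (mean absolute) and the maximum absolute
  distance are reported to cover either aggregation.
- Dice of two empty masks raises rather than silently returning 0.
- Vascular fraction uses the manufacturer ellipsoid centered on the
  active-zone center and aligned with the applicator axis; for
  multi-ablation cases the per-case value is the maximum over the
  per-ablation ellipsoids (one value is reported per case; the rule is
  declared in the output).

## Cohort statistics

- The manufacturer baseline prediction is the union of lookup
  ellipsoids placed on each plan.
- The two-group comparison (vascular fraction >5% vs rest, on the
  identity-line distance of model vs manufacturer volumes) uses the
  Tukey HSD interval, which for two groups is the pooled-variance t
  interval scaled by the studentized-range quantile
  `q(0.95; 2, N-2)/sqrt(2)` (Tukey-Kramer for unbalanced groups). It
  is cross-checked against statsmodels and a permutation oracle in the
  tests. The 5% threshold is configurable (`vf_threshold`); only this
  single pre-specified contrast is tested, so no multiplicity
  correction is applied.
- Scatter correlation is Pearson r.
- Exclusion flags (`gt_overestimated`, `misaligned`) are ground truth
  in synthetic cohorts (set by the generator); no automatic detector
  is attempted for real data, where these artifacts are identified
  visually.
- Whiskers follow the 1.5 IQR box-plot convention.

## Default thermal parameters

| quantity | default | unit | note |
|---|---|---|---|
| liver density rho | 1079 | kg/m^3 | literature value, configurable |
| liver specific heat C_p | 3540 | J/(kg K) | baseline outside the band |
| liver conductivity lambda | 0.52 | W/(m K) | |
| water fraction w | 0.778 | - | sets latent heat of the band |
| latent heat L | 2.26e6 | J/kg | water at ~100 degC |
| evaporation band | 99-100 | degC | rectangle C_p_eff model |
| blood density rho_b | 1060 | kg/m^3 | |
| blood specific heat C_p_b | 3617 | J/(kg K) | |
| arterial temperature T_b | 37 | degC | also initial and boundary |
| baseline perfusion omega0 | 0.0045 | 1/s | hepatic literature value |
| vessel enhancement | 50 | - | the one fixed model constant |

All are generic-population values; patient-specific properties are a
natural extension and every value is a config field.

## Problem sizes

Chosen as the package's own defaults: cohort replays use 20 cases on
2 mm grids (sub-box solves of ~50^3 voxels, automatic ~2-5 s steps),
calibration uses 6 table rows on a 61^3 grid at 2 mm, and the
analytic anchors run at 0.5-1 mm. A full paired sink-on/off 20-case
replay completes in a few minutes on one CPU core; a single-case
simulation takes seconds.

## Known limitations

- The applicator model is a calibrated deposition profile, not an
  electromagnetic solution; absorbed-power redistribution at high
  temperature is heuristic (sigmoid absorption factor).
- The damage-coupled vessel shutdown weakens the heat sink near the
  applicator; a constant-flow vessel model would predict stronger
  indentation.
- Ground-truth fabrication shares the solver with the model under
  test; cohort-level model-vs-ground-truth scores are therefore
  optimistic by construction and are meaningful only for comparing
  the model against the manufacturer baseline under identical truth.
- Masks use voxel-center inclusion; sub-voxel surface effects are
  bounded by one voxel and show up in the +-1 voxel tolerances of the
  geometric tests.
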