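# mwablate

Model-based planning of percutaneous microwave ablation (MWA) in liver,
with the validation machinery needed to compare model predictions
against manufacturer tabulated data on a cohort — exercisable entirely
on synthetic liver/vessel phantoms.

MWA coagulates hepatic tumors by heating tissue around a needle-shaped
applicator. Required power/duration settings are usually chosen from
vendor tables derived ex vivo, which ignore patient anatomy; in vivo,
blood flow in nearby vessels cools the ablation zone (*heat-sink
effect*) and can distort the coagulated volume substantially. This
package implements a biophysical model that accounts for that effect,
and the metrics and cohort statistics used to quantify how much it
matters.

## The model

Temperature on a regular voxel grid follows the Pennes bioheat
equation

```
rho C_p dT/dt = div(lambda grad T) + omega_b rho_b C_p_b (T_b - T) + Q_appl
```

with:

- **Applicator source** `Q_appl`: a simplified axisymmetric deposition
  on the applicator active zone (Gaussian radial falloff, tapered
  axial profile), normalized to `efficiency x power` and attenuated by
  a temperature-dependent absorption factor as tissue desiccates. Its
  free parameters are calibrated so that simulated homogeneous-tissue
  ablations reproduce a manufacturer power/duration table
  (`applicator.calibrate_source`).
- **Perfusion sink**: a distributed perfusion rate `omega_b` over the
  liver, shut down by accumulating thermal damage
  (`omega = omega0 * exp(-Omega)`), and *enhanced by a factor of 50* on
  the segmented vasculature to model the lower flow resistance of
  larger vessels. The vessel sink can be switched off to replay the
  no-vascular-cooling configuration.
- **Evaporation** of tissue water through an effective heat capacity
  over a narrow boiling band; the solver advances enthalpy rather than
  temperature, so latent heat is never skipped and the adiabatic
  energy balance is exact to round-off.
- **Arrhenius damage** `Omega = integral A exp(-Ea/(R T)) dt`;
  `Omega >= 1` defines ablated tissue. Sequential ablations are
  thermally independent and their masks are united.

Validation metrics per case: Dice overlap `2|A^B|/(|A|+|B|)`, signed
surface distance from the predicted-ablation surface to the ground
truth (aggregated as an absolute average error, AAE), relative volume
difference `|dV|/V_gt`, and the *vascular fraction* — the fraction of
the manufacturer reference ellipsoid occupied by segmented vessels, a
pre-simulation proxy for the expected cooling. Cohort statistics:
identity-line distance `(y-x)/x` of model vs manufacturer volumes, a
two-group Tukey 95% range test between high-vascular-fraction cases
(>5%) and the rest, artifact-based exclusions, and box-whisker
summaries.

Because no clinical dataset ships with the package, the `phantom`
module generates the study material: ellipsoidal livers, bifurcating
vessel trees with Murray's-law radii tunable to a target vascular
fraction, applicator plans with 1-6 ablations at 80-100 W and 3-10
min, ground-truth ablations indented near vessels, plus the two
artifacts seen in retrospective clinical analyses (applicator
misalignment from registration error, and triangular infarction wedges
that inflate the apparent ablation).

## Worked example

Simulate one 90 W / 6 min ablation in a synthetic liver with a vessel
tuned to a 10% vascular fraction, fabricate a ground truth from the
sink-enabled physics, and score model vs manufacturer baseline:

```python
import json
from mwablate import applicator as app, phantom as ph, workbench as wb
from mwablate.grid import VoxelGrid

grid = VoxelGrid((56, 56, 56), (2.0, 2.0, 2.0))
case = ph.make_liver_phantom((50, 44, 40), grid, seed=1)
plan = ph.ApplicatorPlan(tip=grid.center_world + (0, 0, 7), direction=(0, 0, 1))
case = case.replace(plans=[plan], settings=[(90.0, 360.0)], case_id="demo")
table = app.default_table()
case = ph.grow_vessel_tree(case, grid.center_world - (30, 0, 0), 3.0, 3,
                           target_vascular_fraction=0.10, seed=1, table=table)
config = wb.RunConfig(seed=1)
case = wb.synthesize_cohort_ground_truth(case, config, table)
result = wb.run_case(config, case, table)
print(json.dumps(result.manifest["metrics"], indent=2, sort_keys=True))
```

prints

```json
{
  "aae_manufacturer_mm": 0.8792994927269427,
  "aae_model_mm": 0.35980743620009015,
  "dice_manufacturer": 0.8560943643512451,
  "dice_model": 0.9163696188648204,
  "rel_vol_diff_manufacturer": 0.2830640335128665,
  "rel_vol_diff_model": 0.18252543387193298,
  "vascular_fraction": 0.09421641791044776
}
```

The model prediction (31.6 mL) sits below the manufacturer ellipsoid
(34.3 mL) because the vessel cools the ablation margin; since the
ground truth was generated with the same heat-sink physics, the model
scores a higher Dice (0.92 vs 0.86) and roughly half the surface error
(0.36 mm vs 0.88 mm AAE) of the vendor-table baseline. On cohorts, the
same comparison is run with the vessel sink enabled and disabled: with
the sink off, model and manufacturer volumes agree closely (Pearson
r > 0.99) and vascular-fraction groups are statistically
indistinguishable; with the sink on, the >5% vascular-fraction group
falls significantly below the identity line.

A thin CLI exposes the pipeline stages (`mwablate phantom|simulate|
evaluate|cohort --config cfg.yaml --seed N`); outputs are NIfTI masks,
CSV tables, JSON manifests (each embedding seed and config hash) and
SVG figures.

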