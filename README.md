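# coroflow

Reduced-order steady haemodynamics of idealized stenosed coronary arteries.

`coroflow` builds parametric lumen geometries for the common morphological
archetypes of coronary artery disease — concentric or eccentric narrowing,
rounded or rectangular longitudinal outline, focal or uniform taper, single
or serial lesions, straight vessels or one-junction bifurcations — and
computes virtual fractional flow reserve (vFFR) with a lumped-parameter
model: Poiseuille viscous losses integrated over the discretized area
profile, a Borda–Carnot post-stenotic expansion loss through an effective
vena contracta per lesion, and a microvascular-resistance outlet boundary.
A study pipeline enumerates the full archetype sweep, classifies
physiological significance (vFFR ≤ 0.80), and writes comparison tables and
a threshold audit.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance surface: reproduction of
the printed vFFR values at ±0.05 under a single frozen configuration, the
qualitative ordering/monotonicity properties, and the exact geometry
criteria.

## Library quick start

```python
from coroflow import (LesionSpec, SegmentSpec, RunConfig,
                      build_area_profile, solve_flow)

cfg = RunConfig()
seg = SegmentSpec(diameter_mm=3.5, length_mm=50.0,
                  lesions=(LesionSpec(ds_fraction=0.7, length_mm=5.0,
                                      center_mm=25.0),))
profile = build_area_profile(seg, cfg.grid_step_mm)
sol = solve_flow(profile, seg.lesions, cfg.make_loss(), cfg.make_fluid(),
                 cfg.make_bc())
print(sol.vffr)   # ~0.90
```

Bifurcations: `BifurcationSpec.from_law(pmb, dmb, law)` sizes the side
branch by Murray, Finet or Huo–Kassab and `solve_branch_flow` returns the
vFFR at both outlets, with the reference microvascular resistance
apportioned by a diameter power law.

## CLI

```bash
coroflow solve vessel.yaml                 # vFFR of one spec (JSON)
coroflow generate vessel.yaml --out p.csv --mesh lumen.stl
coroflow study --out results/             # full sweep -> T2..T6.csv + audit
coroflow audit --results results/         # re-check headline statements
coroflow --config my.yaml solve vessel.yaml
```

Vessel specs are YAML/JSON with the `SegmentSpec`/`BifurcationSpec` field
names; `RunConfig` (pressures, fluid, loss coefficients, grid step,
threshold) round-trips through YAML and stamps every output with its
content hash.

## Model notes

* The vFFR values are produced by a reduced-order model, not 3-D CFD; the
  loss coefficients (`kt`, per-outline contraction coefficients) are frozen
  once in `RunConfig` for the entire sweep.
* Eccentric lesions use a flat-plaque (circle truncated by a chord)
  cross-section with residual height `(1 − ds) · D`; their viscous
  resistance uses the effective circular diameter, which understates the
  resistance of very shallow crescent lumens.
* Branch angle is recorded but carries no physics; junction losses are
  neglected (static-pressure continuity).
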