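# memadh

Mean-field electrostatics and elasticity of lipid membranes near charged,
nanostructured surfaces: a modified Langevin Poisson–Boltzmann solver for the
electric double layer between planar surfaces, a self-consistent model of the
zwitterionic lipid headgroup layer, and an axisymmetric Helfrich shape
minimizer for vesicle adhesion.

## What it computes

- **`memadh.edl`** — the electric double layer between two charged plates in
  a 1:1 electrolyte, with a field-dependent water permittivity from Langevin
  dipole ordering (the relative permittivity falls from its bulk value
  ≈ 78.5 toward n² = 1.77 in strong fields). The osmotic pressure between
  the plates is a conserved first integral of the solution; its constancy
  across the gap is the solver's built-in accuracy diagnostic.
- **`memadh.headgroup`** — a zwitterionic headgroup layer (phosphate plane
  plus a Boltzmann-distributed positive charge at dipole distance D) facing
  a charged wall, solved self-consistently; reports the headgroup
  normalization constant Λ, mean charge position ⟨x⟩, operational tilt angle
  ⟨ω⟩, and the bilayer–wall osmotic pressure.
- **`memadh.vesicle`** — axisymmetric vesicle shapes minimizing the reduced
  Helfrich bending energy with spontaneous curvature and a contact adhesion
  energy, at fixed reduced area and volume: free branches (sphere, prolate,
  oblate, stomatocyte, pear), branch-boundary location by bisection, and
  adhered shapes up to the strong-adhesion pancake limit Ac/A → 1/2.
- **`memadh.oracles`** — independent closed-form and brute-force references
  (linearized double layer, normalization fixed point, contour quadrature)
  used by the test suite.

## Command line

```bash
memadh presets list
memadh edl solve --sigma1 0.2 --sigma2 -0.2 --gap-nm 4 --salt-molar 0.01
memadh edl pressure-curve --preset fig8_low_salt --out results/low_salt
memadh headgroup solve --preset fig10_alpha5
memadh vesicle minimize --v 0.8 --w 4
memadh vesicle transition --pair oblate,prolate --window 0.60,0.70
memadh run --config run.yaml
```

Every command builds a validated run configuration and shares one execution
path with `memadh run`. Outputs are a CSV table plus a JSON metadata sidecar
(written atomically; a failed run leaves no partial files). Exit status: 0
converged, 1 ran but did not converge, 2 invalid input.

A run configuration is a small YAML document:

```yaml
schema_version: 1
module: edl
task: pressure-curve
preset: fig8_low_salt       # optional; params below override preset values
params:
  sigma1: 0.25
output_prefix: results/run1
```

## Python API

```python
from memadh import (ElectrolyteModel, PlanarGap, solve_planar_edl,
                    osmotic_pressure_profile)

model = ElectrolyteModel.from_molar(0.01)
prof = solve_planar_edl(PlanarGap.from_nm(4.0, 0.2, -0.2), model)
pres = osmotic_pressure_profile(prof, model)
print(pres.Pi, pres.constancy_residual)
```

```python
from memadh.vesicle import ReducedShapeProblem, minimize_shape

res = minimize_shape(ReducedShapeProblem(v=0.8, w=4.0), "prolate")
print(res.f, res.shape_class, res.ac_frac, res.contact_curvature)
```

## Verification

`pytest` runs the full suite: unit tests of every primitive against
high-precision references, property-based tests (electroneutrality, pressure
constancy, monotone trends, analytic-gradient checks), and acceptance tests
for the headline numbers (bulk permittivity 78.5, shape-branch boundaries
v* ≈ 0.591 and 0.652, pancake contact limit). The branch boundaries can be
recomputed from scratch with

```bash
python scripts/acceptance.py --seed 0 --out acceptance.json
```

See `docs/methods.md` for the model equations, numerical methods, and known
limitations.
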