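# Methods

This document states the physical models implemented by `memadh`, the
numerical methods used to solve them, and the accuracy diagnostics the
package reports. Reduced (dimensionless) quantities are used for the vesicle
module; SI units everywhere else.

## 1. Electric double layer with orientational water ordering

### Model

Two planar surfaces at `x = 0` and `x = H` carry surface charge densities σ1
and σ2 (A·s/m²) and enclose a 1:1 electrolyte with bulk number density `n0`.
Water is treated as a dense suspension of point dipoles (dipole moment `p0`,
number density `nw`) whose orientational ordering in the local field `E`
produces a field-dependent relative permittivity

```
εr(E) = n² + (nw p0 / ε0) · γ3 · L(γ p0 E β) / E,
γ  = (2 + n²)/2,    γ3 = (2 + n²)/3,    β = 1/(kB T),
```

where `L(u) = coth(u) − 1/u` is the Langevin function and `n` the refractive
index of water. As `E → 0` this reduces to the Onsager-limit bulk value

```
εr,b = n² + nw p0² β γ γ3 / ε0,
```

which evaluates to 78.5 for T = 298 K, p0 = 3.1 Debye (1 D = 3.336·10⁻³⁰
C·m), nw/NA = 55 mol/L and n = 1.33 — the package's default water parameter
set. In strong fields εr(E) falls monotonically toward the optical value n².

The potential solves the modified Poisson–Boltzmann equation

```
d/dx [ ε0 εr(|φ'|) φ' ] = 2 e0 n0 sinh(e0 φ β),
```

with Gauss-law boundary conditions, normals pointing into the electrolyte:

```
ε0 εr φ'(0) = −σ1,      ε0 εr φ'(H) = +σ2.
```

These conditions imply global electroneutrality σ1 + σ2 + ∫ρ dx = 0, which
the test suite verifies as an invariant.

### Osmotic pressure

The pressure between the plates is the conserved first integral of the
boundary-value problem,

```
Π(x) = −ε0 n² E²/2 − nw kT ln( sinh(u)/u ) + 2 n0 kT [cosh(e0 φ β) − 1],
u = γ p0 E β,
```

evaluated at the cell midpoints of the grid (an algebraically equivalent
form writes the ionic term through the ion densities; both are implemented
and tested to agree to round-off). Π is constant across the gap for an exact
solution; the reported `constancy_residual` is

```
(max Π − min Π) / max(|Π̄|, 2 n0 kT),
```

normalized by the larger of the mean pressure and the ideal-gas scale
2 n0 kT so that well-screened gaps (Π → 0) are not judged by a vanishing
denominator. Two cheaper evaluations are available as cross-checks: the
midplane form (valid for equal surface charges, where E = 0 at the midplane)
and a weak-field closed form.

### Numerics

- Conservative finite differences: fluxes `F = ε0 εr(|s|) s` with
  `s = Δφ/Δh` on cell faces, cell-integrated Boltzmann source; the discrete
  residual telescopes so that electroneutrality holds to the Newton
  tolerance.
- Wall-refined grid: a tanh-stretched node distribution concentrates
  resolution in the boundary layers at both walls. By default the node count
  scales with the gap (8000 nodes per nanometre) so the near-wall truncation
  error is independent of H.
- Damped Newton iteration on the banded Jacobian (`scipy` banded solver)
  with backtracking line search; if the full problem stalls, the surface
  charges are ramped up in stages. Iterations that stall at the rounding
  floor of the residual are accepted once the residual is far below the
  physical scale.
- The convergence tolerance is deliberately tight (10⁻¹² of the charge
  scale): Π is a five-digit cancellation between wall terms of order 10⁷ Pa,
  so the Newton floor — not the grid — limits the constancy residual.

Accuracy on the bundled presets: pressure constancy ≤ 2.4·10⁻⁶ across all
gap/salt combinations of the plate presets, Debye–Hückel agreement within 1%
(potential) and 2% (pressure) in the weak-charge regime.

## 2. Zwitterionic headgroup layer

The proximal leaflet's phosphate charges form a surface charge σ1 < 0 at
`x = 0`; each headgroup's positive charge sits a fixed dipole distance D
from the phosphate and is distributed over `0 < x ≤ D` with probability
density

```
P(x) = Λ α e^{−e0 φ β} / (α e^{−e0 φ β} + 1),
(1/D) ∫₀ᴰ P dx = 1,
```

where α is the partition (saturation) parameter and Λ the normalization
constant; Λ → (α+1)/α as φ → 0. The resulting volume charge
`ρZW = |σ1| P/D` enters the planar equation as a fixed source, iterated to
self-consistency with the potential by a Picard loop (mixing 0.7) around the
damped-Newton solver. Default geometry uses D = 0.42 nm, a typical
phosphate–trimethylammonium dipole distance for phosphatidylcholine.

The composite grid carries a node exactly at `x = D` and apportions nodes to
`[0, D]` and `[D, H]` by a square-root rule; the default of 192001 nodes
holds the full-system electroneutrality defect (σ1 + σ2 + ∫ρZW + ∫ρions)
below 10⁻⁶ relative on the reference preset.

The bilayer–wall osmotic pressure uses the same pressure functional but only
on `D ≤ x ≤ H`, where ρZW vanishes and the functional is again a first
integral; inside the headgroup region it is not conserved because of the
source term. Headgroup orientation is reported through the rigid-dipole map
`x = D cos ω`: ⟨ω⟩ = arccos(⟨x⟩/D), so smaller angles mean headgroups
standing more perpendicular to the bilayer. For a negative wall the package
reproduces the expected trends: both the pressure and ⟨ω⟩ decrease as the
wall approaches.

## 3. Axisymmetric vesicle shapes and adhesion

### Model

Shapes are minima of the reduced Helfrich energy with a contact adhesion
term,

```
f = (1/8) ∮ (c1 + c2 − c0)² dA/π  −  (w/2) · (Ac/A·4),
```

in units where the area constraint fixes `A = 4π` (equivalently the
equal-area sphere has radius 1 and energy f = 1 at c0 = 0). Here c1, c2 are
the principal curvatures, c0 the reduced spontaneous curvature, and
`w = W Rs²/κ` the reduced adhesion strength (W adhesion energy per area, Rs
the equal-area sphere radius, κ the bending modulus). The adhered region is
a flat disc of radius r_c on the substrate plane; its reduced contact area
is `ac_frac = Ac/A = r_c²/4 ≤ 1/2`.

The free contour is parametrized by the tangent angle along normalized arc
length,

```
ψ(t) = π t + Σₖ aₖ sin(kπt),      s = L t,
```

which builds in smooth poles; `r(t)` follows by integrating `cos ψ` from the
closed top pole, and the contact disc radius is `r_c = r(0)`. Area, volume,
curvatures and the energy are evaluated by trapezoid quadrature on a uniform
t-grid (1200 intervals by default, 40 Fourier modes).

### Minimization

`scipy`'s SLSQP minimizes the energy over `(a₁…a_M, L)` subject to equality
constraints on reduced area (= 1) and reduced volume (= v), with analytic
gradients obtained by an adjoint recursion through the cumulative radius
integral (verified against finite differences in the test suite). Two
numerical safeguards matter:

- The objective is scaled by `1/(1 + w)` so SLSQP's merit function balances
  the O(w) adhesion energy against the O(1) constraints; without this the
  strong-adhesion (pancake) regime fails to converge.
- A shape with r_c = 0 is stationary against opening a contact disc (gain
  and cost are both quadratic in the disc radius), so a gradient method
  never opens one spontaneously. A closed shape with pole curvature c1(0)
  binds only for `w > 2 c1(0)²`. Whenever w exceeds a conservative lower
  bound (c1(0)²/2) the minimizer restarts from the converged contour with a
  small disc cut open — trying both the contour and its up-down mirror
  (aₖ → (−1)ᵏ aₖ), since the two poles generally have different curvatures —
  and keeps the lower-energy outcome.

Seeds exist for the sphere, prolate, oblate, stomatocyte, pancake and pear
branches; the pear seed is built from two externally tangent spheres
(r1² + r2² = 1, r1³ + r2³ = v) with a smoothed neck. Branch boundaries are
located by continuation along each branch and bisection of the energy
difference; at c0 = 0, w = 0 the package finds the stomatocyte/oblate
boundary at v* = 0.591 and the oblate/prolate boundary at v* = 0.651, and at
v = 0.1 the strongly adhered pancake reaches ac_frac ≥ 0.45, increasing
toward the geometric bound 1/2 with w.

At an adhered minimum the transversality condition at the contact line fixes
the meridional contact curvature, `c1* = √(2w)`. The discrete c1(0)
converges to this slowly (the contact boundary layer is resolved at
first order in the mode count), so the 2% agreement verified by the tests
holds for moderate w at the default resolution; very large w needs more
modes for the same relative accuracy.

## 4. Workbench

All computations are reachable through validated run configurations
(`pydantic` schema, unknown keys rejected, preset/module consistency
checked). The CLI builds the same configuration objects, so file-driven and
flag-driven runs share one execution path. Outputs (CSV table + JSON
metadata with the fully resolved parameter set) are written atomically —
temp file then rename — so failed runs never leave partial files, and
repeated runs are byte-identical.

## 5. Limitations

- 1:1 electrolyte only; no ion-specific sizes beyond the saturation built
  into the Langevin closure; no image-charge or correlation effects.
- The headgroup layer is laterally uniform (mean field); headgroup–headgroup
  correlations and finite lateral density effects are absorbed into α.
- Vesicle shapes are axisymmetric by construction; non-axisymmetric
  (e.g. starfish) branches are out of scope. The substrate is flat and the
  adhesion potential is a contact energy.
- Pressure constancy is guaranteed at the 10⁻⁵ level for the bundled preset
  parameter ranges; strongly asymmetric, very high surface charges can stall
  the Newton iteration at a larger floor.
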