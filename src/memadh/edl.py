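"""Modified Langevin Poisson-Boltzmann (LPB) electric double layer, planar geometry.

The model generalizes classical Poisson-Boltzmann theory for point-like
monovalent ions by treating water as Langevin dipoles with cavity-field and
electronic-polarizability corrections.  The relative permittivity becomes
field dependent,

    eps_r(E) = n^2 + (n_w p0 / eps0) ((2 + n^2)/3) L(gamma p0 E beta) / E,

with L(u) = coth(u) - 1/u the Langevin function and gamma = (2 + n^2)/2,
so the permittivity drops from the Onsager bulk value toward n^2 where the
field saturates the dipoles (i.e. near strongly charged surfaces).

The planar boundary-value problem between two charged walls is discretized
with a conservative finite-difference scheme on a wall-refined grid and
solved by damped Newton iteration; the flux variable eps0*eps_r(E)*dphi/dx
is treated exactly, which makes discrete electroneutrality hold to the
Newton tolerance.  The osmotic pressure functional (the first integral of
the planar equation, i.e. the contact theorem) is evaluated pointwise at the
cell midpoints where the scheme is second-order accurate.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import E0, EPS0
from .models import ElectrolyteModel, FieldProfile, PlanarGap, PressureResult

__all__ = [
    "langevin",
    "langevin_over_u",
    "dlangevin",
    "ln_sinhc",
    "bulk_permittivity",
    "field_permittivity",
    "ion_densities",
    "make_grid",
    "solve_planar_edl",
    "osmotic_pressure_pointwise",
    "osmotic_pressure_profile",
    "osmotic_pressure_midplane",
    "osmotic_pressure_weakfield",
    "pressure_distance_curve",
]

# Boltzmann factors are clipped at this reduced-potential magnitude (never
# silently: the solver flags the profile).
PHI_CLIP = 50.0

_SMALL_U = 1e-3


def langevin(u):
    """Langevin function L(u) = coth(u) - 1/u.

    Odd, saturates to +-1; evaluated by its Taylor series for |u| < 1e-3 to
    avoid catastrophic cancellation near zero.
    """
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = np.abs(u) < _SMALL_U
    us = u[small]
    out[small] = us / 3.0 - us**3 / 45.0 + 2.0 * us**5 / 945.0
    ub = u[~small]
    # coth via tanh is stable; tanh saturates for |u| > ~20 with no overflow
    out[~small] = 1.0 / np.tanh(ub) - 1.0 / ub
    return out if out.ndim else float(out)


def langevin_over_u(u):
    """L(u)/u, finite at u = 0 (limit 1/3)."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = np.abs(u) < _SMALL_U
    us = u[small]
    out[small] = 1.0 / 3.0 - us**2 / 45.0 + 2.0 * us**4 / 945.0
    ub = u[~small]
    out[~small] = (1.0 / np.tanh(ub) - 1.0 / ub) / ub
    return out if out.ndim else float(out)


def dlangevin(u):
    """Derivative L'(u) = 1/u^2 - 1/sinh(u)^2 (even, in (0, 1/3])."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    au = np.abs(u)
    small = au < _SMALL_U
    us = u[small]
    out[small] = 1.0 / 3.0 - us**2 / 15.0 + 2.0 * us**4 / 189.0
    big = au > 350.0  # sinh overflows near 710; L' ~ 1/u^2 long before
    out[big] = 1.0 / u[big] ** 2
    mid = ~(small | big)
    um = u[mid]
    out[mid] = 1.0 / um**2 - 1.0 / np.sinh(um) ** 2
    return out if out.ndim else float(out)


def ln_sinhc(u):
    """ln(sinh(u)/u), the entropic dipole term of the pressure functional."""
    u = np.abs(np.asarray(u, dtype=float))
    out = np.empty_like(u)
    small = u < _SMALL_U
    us = u[small]
    out[small] = us**2 / 6.0 - us**4 / 180.0
    big = u > 30.0
    ub = u[big]
    out[big] = ub - np.log(2.0 * ub) + np.log1p(-np.exp(-2.0 * ub))
    mid = ~(small | big)
    um = u[mid]
    out[mid] = np.log(np.sinh(um) / um)
    return out if out.ndim else float(out)


def bulk_permittivity(model: ElectrolyteModel) -> float:
    """Onsager-limit bulk relative permittivity (zero-field limit of eps_r(E))."""
    return model.eps_r_bulk


def field_permittivity(E, model: ElectrolyteModel):
    """Field-dependent relative permittivity eps_r(E) of the LPB closure.

    Strictly decreasing in E, bounded between n^2 (saturation) and the bulk
    Onsager value (E -> 0).
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("field magnitude E must be non-negative")
    u = model.gamma * model.p0 * model.beta * E
    # L(u)/E = gamma*p0*beta * L(u)/u, so the E->0 limit is handled by series
    val = model.n_refr**2 + (
        model.nw * model.p0**2 * model.gamma * model.gamma3 * model.beta / EPS0
    ) * langevin_over_u(u)
    return val if np.ndim(val) else float(val)


def ion_densities(phi, model: ElectrolyteModel, clip: float = PHI_CLIP):
    """Boltzmann cation/anion number densities n+- = n0 exp(-+ e0 phi beta).

    Reduced potentials beyond ``clip`` are clipped (guarded overflow); the
    returned flag reports whether clipping occurred.
    """
    phi = np.asarray(phi, dtype=float)
    u = E0 * phi * model.beta
    clipped = bool(np.any(np.abs(u) > clip))
    uc = np.clip(u, -clip, clip)
    n_plus = model.n0 * np.exp(-uc)
    n_minus = model.n0 * np.exp(uc)
    return n_plus, n_minus, clipped


# ---------------------------------------------------------------------------
# Nonlinear flux F(s) = eps0 eps_r(|s|) s for s = dphi/dx
# ---------------------------------------------------------------------------

def _flux(s, model: ElectrolyteModel):
    """eps0 * eps_r(|s|) * s: odd, strictly increasing in s."""
    u = model.gamma * model.p0 * model.beta * s
    return EPS0 * model.n_refr**2 * s + model.nw * model.p0 * model.gamma3 * langevin(u)


def _dflux(s, model: ElectrolyteModel):
    u = model.gamma * model.p0 * model.beta * s
    return (
        EPS0 * model.n_refr**2
        + model.nw * model.p0**2 * model.gamma3 * model.gamma * model.beta * dlangevin(u)
    )


def _wall_field(sigma: float, model: ElectrolyteModel) -> float:
    """Invert F(s) = sigma (Newton; F is smooth, odd, strictly increasing)."""
    s = sigma / (EPS0 * model.eps_r_bulk)
    for _ in range(100):
        f = _flux(s, model) - sigma
        ds = f / _dflux(s, model)
        s -= ds
        if abs(ds) <= 1e-14 * (abs(s) + 1e-30):
            break
    return s


def make_grid(H: float, n_nodes: int = 8001, stretch: float = 4.0) -> np.ndarray:
    """Wall-refined grid on [0, H]: tanh clustering toward both walls."""
    if n_nodes < 3:
        raise ValueError("need at least 3 grid nodes")
    xi = np.linspace(-1.0, 1.0, n_nodes)
    g = np.tanh(stretch * xi) / np.tanh(stretch)
    x = 0.5 * H * (1.0 + g)
    x[0], x[-1] = 0.0, H
    return x


def _newton_solve(
    x: np.ndarray,
    model: ElectrolyteModel,
    sigma1: float,
    sigma2: float,
    rho_fixed_cell: Optional[np.ndarray],
    phi0: Optional[np.ndarray],
    max_iter: int,
    tol_factor: float,
):
    """Damped Newton on the conservative FD residual; returns (phi, res, hist, ok)."""
    from scipy.linalg import solve_banded

    n = x.size
    h = np.diff(x)
    m = np.empty(n)  # cell sizes (half cells at walls)
    m[0] = h[0] / 2.0
    m[-1] = h[-1] / 2.0
    m[1:-1] = (h[:-1] + h[1:]) / 2.0

    rz = np.zeros(n) if rho_fixed_cell is None else rho_fixed_cell
    e0b = E0 * model.beta
    two_en0 = 2.0 * E0 * model.n0

    scale = max(abs(sigma1), abs(sigma2), two_en0 * (x[-1] - x[0]), 1e-8)
    tol = tol_factor * scale
    stall_tol = 1e-8 * scale  # accept a stalled iteration at the rounding floor

    phi = np.zeros(n) if phi0 is None else phi0.copy()

    def residual(p):
        s = np.diff(p) / h
        G = _flux(s, model)
        u = np.clip(e0b * p, -PHI_CLIP, PHI_CLIP)
        src = m * two_en0 * np.sinh(u) - rz  # cell-integrated source
        R = np.empty(n)
        R[0] = G[0] + sigma1 - src[0]
        R[1:-1] = G[1:] - G[:-1] - src[1:-1]
        R[-1] = sigma2 - G[-1] - src[-1]
        return R, s

    R, s = residual(phi)
    hist = [float(np.max(np.abs(R)))]
    ok = hist[-1] < tol
    it = 0
    while not ok and it < max_iter:
        it += 1
        dG = _dflux(s, model) / h
        u = np.clip(e0b * phi, -PHI_CLIP, PHI_CLIP)
        dsrc = m * two_en0 * e0b * np.cosh(u)
        # banded Jacobian (ab[0]=super, ab[1]=diag, ab[2]=sub)
        ab = np.zeros((3, n))
        ab[1, 0] = -dG[0] - dsrc[0]
        ab[0, 1] = dG[0]
        ab[1, 1:-1] = -dG[1:] - dG[:-1] - dsrc[1:-1]
        ab[1, -1] = -dG[-1] - dsrc[-1]
        ab[0, 2:] = dG[1:]
        ab[2, 0:-1] = dG  # J[i, i-1] = dG[i-1], stored at ab[2, i-1]
        dphi = solve_banded((1, 1), ab, -R)
        lam, r0 = 1.0, hist[-1]
        for _ in range(40):
            trial = phi + lam * dphi
            Rt, st = residual(trial)
            rt = float(np.max(np.abs(Rt)))
            if rt < r0 * (1.0 - 1e-4 * lam) or rt < tol:
                break
            lam *= 0.5
        if rt >= r0 * (1.0 - 1e-12) and r0 < stall_tol:
            ok = True  # rounding floor reached
            break
        phi, R, s = trial, Rt, st
        hist.append(rt)
        ok = rt < tol
    return phi, hist[-1], hist, ok, s


def solve_planar_edl(
    gap: PlanarGap,
    model: ElectrolyteModel,
    n_nodes: Optional[int] = None,
    stretch: float = 4.0,
    x: Optional[np.ndarray] = None,
    rho_fixed_cell: Optional[np.ndarray] = None,
    phi0: Optional[np.ndarray] = None,
    max_iter: int = 60,
    tol_factor: float = 1e-12,
    ramp_steps: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
) -> FieldProfile:
    """Solve the planar modified-LPB boundary-value problem.

    Boundary conditions are Gauss-law conditions at both walls (electric
    displacement equals the wall charge density, normals pointing into the
    electrolyte): F(dphi/dx)|_0 = -sigma1, F(dphi/dx)|_H = +sigma2, with
    F the nonlinear flux eps0*eps_r*dphi/dx.  If the direct damped-Newton
    solve stalls, the surface charges are ramped in steps.

    ``rho_fixed_cell`` optionally supplies an additional fixed volume charge,
    given as cell integrals (C/m^2 per node cell), used by the headgroup model.

    The default grid scales with the gap (about 8000 nodes per nm), which
    keeps the near-wall discretization error of the pressure functional
    independent of H.
    """
    if x is None:
        if n_nodes is None:
            n_nodes = 8000 * max(1, int(np.ceil(gap.H / 1e-9))) + 1
        x = make_grid(gap.H, n_nodes=n_nodes, stretch=stretch)
    if x.size < 3:
        raise ValueError("gap must span at least 2 grid cells")

    phi, res, hist, ok, s = _newton_solve(
        x, model, gap.sigma1, gap.sigma2, rho_fixed_cell, phi0, max_iter, tol_factor
    )
    if not ok:
        # continuation in surface charge (and fixed charge) magnitude
        phi_r = np.zeros_like(x) if phi0 is None else phi0.copy()
        hist_all = list(hist)
        for fr in ramp_steps:
            rz = None if rho_fixed_cell is None else fr * rho_fixed_cell
            phi_r, res, hist, ok, s = _newton_solve(
                x, model, fr * gap.sigma1, fr * gap.sigma2, rz, phi_r,
                max_iter, tol_factor,
            )
            hist_all.extend(hist)
            if not ok:
                break
        phi, hist = phi_r, hist_all
    if not ok:
        raise RuntimeError(
            "planar LPB solver failed to converge; residual history: "
            f"{[f'{r:.3e}' for r in hist[-8:]]}"
        )

    h = np.diff(x)
    x_mid = 0.5 * (x[:-1] + x[1:])
    phi_mid = 0.5 * (phi[:-1] + phi[1:])
    E_mid = np.abs(s)
    # node fields: exact wall values from the Gauss condition, interior from
    # distance-weighted face averages
    E_nodes = np.empty_like(phi)
    E_nodes[0] = abs(_wall_field(-gap.sigma1, model))
    E_nodes[-1] = abs(_wall_field(gap.sigma2, model))
    wgt = h[:-1] / (h[:-1] + h[1:])
    E_nodes[1:-1] = np.abs((1 - wgt) * s[:-1] + wgt * s[1:])

    n_plus, n_minus, clipped = ion_densities(phi, model)
    prof = FieldProfile(
        x=x,
        phi=phi,
        E=E_nodes,
        eps_r=field_permittivity(E_nodes, model),
        n_plus=n_plus,
        n_minus=n_minus,
        rho=E0 * (n_plus - n_minus),
        converged=ok,
        residual=res,
        clipped=clipped,
        gap=gap,
        iterations=len(hist),
        x_mid=x_mid,
        phi_mid=phi_mid,
        E_mid=E_mid,
        residual_history=hist,
    )
    return prof


# ---------------------------------------------------------------------------
# Osmotic pressure functionals
# ---------------------------------------------------------------------------

def osmotic_pressure_pointwise(
    profile: FieldProfile, model: ElectrolyteModel, use_densities: bool = False
) -> np.ndarray:
    """Pointwise osmotic pressure functional at the cell midpoints.

    Four terms: electronic field term, ionic osmotic term, Langevin dipole
    term and the entropic ln-sinh term.  ``use_densities`` evaluates the
    ionic term through the Boltzmann densities n+ + n- - 2 n0 instead of
    2 n0 (cosh - 1); the two forms are algebraically identical.
    """
    E = profile.E_mid
    phi = profile.phi_mid
    u = model.gamma * model.p0 * model.beta * E
    t1 = -0.5 * EPS0 * model.n_refr**2 * E**2
    if use_densities:
        npl, nmi, _ = ion_densities(phi, model)
        t2 = model.kT * (npl + nmi - 2.0 * model.n0)
    else:
        t2 = 2.0 * model.n0 * model.kT * (
            np.cosh(np.clip(E0 * phi * model.beta, -PHI_CLIP, PHI_CLIP)) - 1.0
        )
    t3 = -model.nw * model.p0 * model.gamma3 * E * langevin(u)
    t4 = (model.gamma3 * model.nw / (model.gamma * model.beta)) * ln_sinhc(u)
    return t1 + t2 + t3 + t4


def _constancy(pi: np.ndarray, model: ElectrolyteModel) -> float:
    """Pointwise spread of the pressure functional, relative to the local
    pressure scale max(|Pi|, 2 n0 kT) of the first integral K = Pi + 2 n0 kT
    (a pure |Pi| normalization would blow up for well-screened gaps where
    Pi -> 0 while K stays finite)."""
    mean = float(np.mean(pi))
    scale = max(abs(mean), 2.0 * model.n0 * model.kT)
    return float((np.max(pi) - np.min(pi)) / scale)


def _require_converged(profile: FieldProfile) -> None:
    if not profile.converged:
        raise ValueError(
            f"profile not converged (residual {profile.residual:.3e}); "
            "refusing to evaluate the pressure functional"
        )


def osmotic_pressure_profile(
    profile: FieldProfile, model: ElectrolyteModel
) -> PressureResult:
    """Full pressure functional, gap-averaged, with its contact-theorem residual."""
    _require_converged(profile)
    pi = osmotic_pressure_pointwise(profile, model)
    Pi = float(np.mean(pi))
    return PressureResult(
        Pi=Pi,
        K=Pi + 2.0 * model.n0 * model.kT,
        constancy_residual=_constancy(pi, model),
        method="full",
        pointwise=pi,
        x_eval=profile.x_mid,
    )


def osmotic_pressure_midplane(
    profile: FieldProfile, model: ElectrolyteModel
) -> PressureResult:
    """Equal-charge shortcut: Pi = 2 n0 kT (cosh(e0 phi(H/2) beta) - 1) >= 0.

    Valid because for sigma1 = sigma2 the field vanishes at the midplane.
    """
    _require_converged(profile)
    g = profile.gap
    if abs(g.sigma1 - g.sigma2) > 1e-9 * max(abs(g.sigma1), abs(g.sigma2), 1e-12):
        raise ValueError("midplane form requires sigma1 == sigma2")
    phi_m = float(np.interp(g.H / 2.0, profile.x, profile.phi))
    Pi = 2.0 * model.n0 * model.kT * (np.cosh(E0 * phi_m * model.beta) - 1.0)
    pi = osmotic_pressure_pointwise(profile, model)
    return PressureResult(
        Pi=float(Pi),
        K=float(Pi) + 2.0 * model.n0 * model.kT,
        constancy_residual=_constancy(pi, model),
        method="midplane",
    )


def osmotic_pressure_weakfield(
    profile: FieldProfile, model: ElectrolyteModel
) -> PressureResult:
    """Weak-field expansion evaluated at the x = H wall.

    Pi ~ -sigma2^2/(2 eps0 eps_rb) + 2 n0 kT (cosh(e0 phi(H) beta) - 1).
    The reported quality metric is the maximum expansion parameter
    gamma p0 E beta over the gap (the expansion needs it small).
    """
    _require_converged(profile)
    g = profile.gap
    phi_H = float(profile.phi[-1])
    Pi = -g.sigma2**2 / (2.0 * EPS0 * model.eps_r_bulk) + 2.0 * model.n0 * model.kT * (
        np.cosh(E0 * phi_H * model.beta) - 1.0
    )
    quality = float(np.max(model.gamma * model.p0 * model.beta * profile.E_mid))
    return PressureResult(
        Pi=float(Pi),
        K=float(Pi) + 2.0 * model.n0 * model.kT,
        constancy_residual=np.nan,
        method="weakfield",
        quality=quality,
    )


def pressure_distance_curve(
    model: ElectrolyteModel,
    sigma1: float,
    sigma2: float,
    H_list: Sequence[float],
    n_nodes: Optional[int] = None,
    stretch: float = 4.0,
) -> pd.DataFrame:
    """Osmotic pressure versus wall separation; per-row failures are recorded.

    Returns a DataFrame with columns H, Pi, K, constancy_residual, converged.
    """
    rows = []
    for H in H_list:
        try:
            prof = solve_planar_edl(
                PlanarGap(H=H, sigma1=sigma1, sigma2=sigma2),
                model,
                n_nodes=n_nodes,
                stretch=stretch,
            )
            pr = osmotic_pressure_profile(prof, model)
            rows.append(
                dict(H=H, Pi=pr.Pi, K=pr.K,
                     constancy_residual=pr.constancy_residual, converged=True)
            )
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            rows.append(
                dict(H=H, Pi=np.nan, K=np.nan, constancy_residual=np.nan,
                     converged=False, error=str(exc))
            )
    df = pd.DataFrame(rows)
    good = df[df.converged]
    if len(good) > 1:
        order = good.sort_values("H")
        df.attrs["abs_Pi_increases_as_H_decreases"] = bool(
            np.all(np.diff(np.abs(order.Pi.to_numpy())) <= 0)
        )
    return df
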