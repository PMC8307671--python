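"""Zwitterionic lipid headgroup layer against a charged wall.

The phosphate charges of the proximal leaflet are a surface charge sigma1 < 0
at x = 0.  The positive trimethylammonium charge of each headgroup sits at a
fixed distance D from the phosphate and is distributed over 0 < x <= D with a
Boltzmann-weighted, finite-size-corrected probability density

    P(x) = Lambda * alpha exp(-e0 phi beta) / (alpha exp(-e0 phi beta) + 1),

normalized so (1/D) int_0^D P dx = 1.  The resulting volume charge
rho_zw(x) = |sigma1| P(x)/D enters the planar LPB equation as a fixed source
that is iterated to self-consistency with the potential (Picard outer loop
around the damped-Newton boundary-value solve).

The osmotic pressure between the headgroup layer and the wall is the ordinary
pressure functional evaluated only on [D, H], where rho_zw vanishes and the
functional is a first integral (constant); inside the headgroup region the
functional is not conserved because of the zwitterionic source term.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from .constants import E0
from . import edl
from .models import (
    ElectrolyteModel,
    HeadgroupModel,
    HeadgroupProfile,
    PressureResult,
)

__all__ = [
    "normalization_constant",
    "partition_density",
    "solve_headgroup_edl",
    "bilayer_wall_pressure",
    "headgroup_orientation",
    "make_headgroup_grid",
]


def partition_density(phi, alpha: float, electrolyte: ElectrolyteModel):
    """Unnormalized headgroup density g(x) = alpha e^{-u}/(alpha e^{-u} + 1).

    ``u`` is the reduced potential e0 phi beta; writing the ratio through
    1/(1 + e^{u}/alpha) keeps it stable for large |u|.
    """
    u = np.asarray(phi, dtype=float) * E0 * electrolyte.beta
    return 1.0 / (1.0 + np.exp(np.clip(u, -edl.PHI_CLIP, edl.PHI_CLIP)) / alpha)


def normalization_constant(
    x: np.ndarray,
    phi: np.ndarray,
    model: HeadgroupModel,
    electrolyte: ElectrolyteModel,
) -> float:
    """Normalization constant Lambda of the headgroup probability density.

    Determined from (1/D) int_0^D Lambda g(x) dx = 1 with trapezoid quadrature
    on the sub-grid x <= D (the solver grid always carries a node at D).
    """
    sel = x <= model.D * (1.0 + 1e-12)
    g = partition_density(phi[sel], model.alpha, electrolyte)
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite headgroup integrand")
    integral = np.trapezoid(g, x[sel])
    return float(model.D / integral)


def make_headgroup_grid(
    model: HeadgroupModel, n_nodes: int = 192001, stretch: float = 3.0
) -> np.ndarray:
    """Composite wall-refined grid on [0, H] with a node exactly at x = D.

    Nodes are apportioned to [0, D] and [D, H] in proportion to a sqrt rule
    so the thin headgroup region keeps adequate resolution.
    """
    frac = model.D / model.H
    n1 = int(np.clip(round(n_nodes * np.sqrt(frac)), 64, n_nodes - 64))
    n2 = n_nodes - n1 + 1
    g1 = edl.make_grid(model.D, n_nodes=n1, stretch=stretch)
    g2 = edl.make_grid(model.H - model.D, n_nodes=n2, stretch=stretch) + model.D
    return np.concatenate([g1, g2[1:]])


def solve_headgroup_edl(
    model: HeadgroupModel,
    electrolyte: ElectrolyteModel,
    n_nodes: int = 192001,
    stretch: float = 3.0,
    max_outer: int = 200,
    mix: float = 0.7,
    outer_tol: float = 1e-10,
) -> HeadgroupProfile:
    """Self-consistent headgroup + electrolyte double layer.

    Picard outer loop: the headgroup charge density rho_zw derived from the
    current potential is mixed into the source of the boundary-value problem
    until the density is stationary; each inner solve is the damped-Newton
    planar LPB solver.  Discrete headgroup charge conservation
    (int rho_zw = |sigma1|) is built into the cell quadrature, so full-system
    electroneutrality holds to the Newton tolerance.
    """
    x = make_headgroup_grid(model, n_nodes=n_nodes, stretch=stretch)
    i_D = int(np.argmin(np.abs(x - model.D)))
    n = x.size
    h = np.diff(x)
    # trapezoid weights restricted to [0, D]; these match the solver's cell
    # quadrature (half cells at segment ends), so sum(w * rho) = trapz exactly
    w_D = np.zeros(n)
    w_D[0] = h[0] / 2.0
    w_D[1:i_D] = (h[:i_D - 1] + h[1:i_D]) / 2.0
    w_D[i_D] = h[i_D - 1] / 2.0

    phi = np.zeros(n)
    P = np.zeros(n)
    Lambda = (model.alpha + 1.0) / model.alpha
    P[: i_D + 1] = 1.0  # zero-potential start: uniform density
    defect = np.inf
    base = None
    it = 0
    converged = False
    for it in range(1, max_outer + 1):
        rho_zw = np.abs(model.sigma1) * P / model.D
        rho_cell = w_D * rho_zw
        base = edl.solve_planar_edl(
            model.gap,
            electrolyte,
            x=x,
            rho_fixed_cell=rho_cell,
            phi0=phi,
        )
        phi = base.phi
        Lambda = normalization_constant(x, phi, model, electrolyte)
        P_new = np.zeros(n)
        P_new[: i_D + 1] = Lambda * partition_density(
            phi[: i_D + 1], model.alpha, electrolyte
        )
        defect = float(np.max(np.abs(P_new - P)))
        P = P + mix * (P_new - P)
        if defect < outer_tol:
            P = P_new
            converged = True
            break

    rho_zw = np.abs(model.sigma1) * P / model.D
    # normalization defect of the reported density (should be ~ round-off)
    norm_def = abs(np.trapezoid(P[: i_D + 1], x[: i_D + 1]) / model.D - 1.0)
    mean_x = float(
        np.trapezoid(x[: i_D + 1] * P[: i_D + 1], x[: i_D + 1]) / model.D
    )
    ratio = mean_x / model.D
    if not (0.0 < ratio <= 1.0 + 1e-9):
        raise RuntimeError(f"headgroup first moment out of range: <x>/D = {ratio}")
    mean_omega = float(np.arccos(np.clip(ratio, 0.0, 1.0)))

    if not converged:
        raise RuntimeError(
            f"headgroup self-consistency loop did not converge in {max_outer} "
            f"iterations (last density defect {defect:.3e}, Lambda {Lambda:.6g})"
        )
    return HeadgroupProfile(
        base=base,
        Lambda=Lambda,
        P=P,
        rho_zw=rho_zw,
        mean_x=mean_x,
        mean_omega=mean_omega,
        i_D=i_D,
        model=model,
        outer_iterations=it,
        outer_converged=converged,
        normalization_defect=norm_def,
    )


def bilayer_wall_pressure(
    profile: HeadgroupProfile, electrolyte: ElectrolyteModel
) -> PressureResult:
    """Osmotic pressure between the headgroup layer and the wall.

    The pressure functional is evaluated pointwise on D <= x <= H only (the
    region free of headgroup charge, where it is a conserved first integral);
    its constancy there is reported as the residual.
    """
    if not profile.converged:
        raise ValueError("profile not converged; refusing pressure evaluation")
    base = profile.base
    pi_all = edl.osmotic_pressure_pointwise(base, electrolyte)
    sel = base.x_mid >= profile.model.D
    if np.count_nonzero(sel) < 10:
        raise ValueError("fewer than 10 grid nodes in [D, H]; refine the grid")
    pi = pi_all[sel]
    Pi = float(np.mean(pi))
    scale = max(abs(Pi), 1e-9 * 2.0 * electrolyte.n0 * electrolyte.kT)
    return PressureResult(
        Pi=Pi,
        K=Pi + 2.0 * electrolyte.n0 * electrolyte.kT,
        constancy_residual=float((np.max(pi) - np.min(pi)) / scale),
        method="full",
        pointwise=pi,
        x_eval=base.x_mid[sel],
    )


def headgroup_orientation(profile: HeadgroupProfile) -> tuple[float, float]:
    """Mean positive-charge position <x> and operational tilt angle <omega>.

    The rigid headgroup dipole of length D maps position to orientation via
    x = D cos(omega), so <omega> := arccos(<x>/D), clipped to [0, pi/2];
    smaller angles mean headgroups standing more perpendicular to the bilayer.
    """
    if not profile.converged:
        raise ValueError("profile not converged")
    return profile.mean_x, min(profile.mean_omega, np.pi / 2.0)
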