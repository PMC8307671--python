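"""Independent brute-force oracles used by the test suite.

Each oracle deliberately avoids the code paths of the production solvers:
the Debye-Hueckel oracle is a closed form, the normalization oracle is a
fixed-point iteration with its own quadrature, and the contour oracle
re-evaluates the tangent-angle series on a fine uniform grid with plain
trapezoid sums.
"""
from __future__ import annotations

import numpy as np

from .constants import E0, EPS0
from .models import ElectrolyteModel, FieldProfile, PlanarGap

__all__ = [
    "debye_huckel_oracle",
    "debye_huckel_pressure",
    "normalization_oracle",
    "contour_area_volume_oracle",
]


def _dh_coefficients(gap: PlanarGap, model: ElectrolyteModel):
    """Coefficients of phi = A cosh(kappa x) + B sinh(kappa x)."""
    eps = EPS0 * model.eps_r_bulk
    kappa = 1.0 / model.debye_length
    # Gauss law with normals pointing into the electrolyte:
    #   at x = 0 (normal +x):  -eps phi'(0) = sigma1  =>  phi'(0) = -sigma1/eps
    B = -gap.sigma1 / (eps * kappa)
    kH = kappa * gap.H
    #   at x = H (normal -x):   eps phi'(H) = sigma2  =>  phi'(H) = sigma2/eps
    A = (gap.sigma2 / (eps * kappa) - B * np.cosh(kH)) / np.sinh(kH)
    return A, B, kappa


def debye_huckel_oracle(
    gap: PlanarGap, model: ElectrolyteModel, n_nodes: int = 2001
) -> FieldProfile:
    """Closed-form linearized (Debye-Hueckel) two-plate profile.

    Constant bulk permittivity, screening length from n0 and T.  Valid as a
    comparison target only in the weak-charge regime.
    """
    A, B, kappa = _dh_coefficients(gap, model)
    x = np.linspace(0.0, gap.H, n_nodes)
    phi = A * np.cosh(kappa * x) + B * np.sinh(kappa * x)
    dphi = kappa * (A * np.sinh(kappa * x) + B * np.cosh(kappa * x))
    E = np.abs(dphi)
    u = E0 * phi * model.beta
    n_plus = model.n0 * np.exp(-u)
    n_minus = model.n0 * np.exp(u)
    return FieldProfile(
        x=x,
        phi=phi,
        E=E,
        eps_r=np.full_like(x, model.eps_r_bulk),
        n_plus=n_plus,
        n_minus=n_minus,
        rho=E0 * (n_plus - n_minus),
        converged=True,
        residual=0.0,
        clipped=False,
        gap=gap,
    )


def debye_huckel_pressure(gap: PlanarGap, model: ElectrolyteModel) -> float:
    """Closed-form linearized osmotic pressure between the two plates (Pa).

    For phi = A cosh + B sinh the quadratic pressure functional
    -eps phi'^2/2 + eps kappa^2 phi^2/2 is exactly constant and equals
    eps kappa^2 (A^2 - B^2)/2.
    """
    A, B, kappa = _dh_coefficients(gap, model)
    return 0.5 * EPS0 * model.eps_r_bulk * kappa**2 * (A**2 - B**2)


def normalization_oracle(
    x: np.ndarray,
    phi: np.ndarray,
    D: float,
    alpha: float,
    electrolyte: ElectrolyteModel,
    n_fine: int = 200001,
    max_iter: int = 200,
    tol: float = 1e-13,
) -> float:
    """Normalization constant by fixed-point iteration on its own fine grid.

    Interpolates the potential onto a uniform grid over [0, D] and iterates
    Lambda <- Lambda / ((1/D) int Lambda g dx) with Simpson quadrature until
    stationary.  Independent of the trapezoid cell quadrature of the solver.
    """
    from scipy.integrate import simpson
    from scipy.interpolate import interp1d

    xf = np.linspace(0.0, D, n_fine)
    phif = interp1d(x, phi, kind="cubic")(xf)
    u = E0 * phif * electrolyte.beta
    g = 1.0 / (1.0 + np.exp(np.clip(u, -50, 50)) / alpha)
    lam = 1.0
    for _ in range(max_iter):
        mean = simpson(lam * g, x=xf) / D
        lam_new = lam / mean
        if abs(lam_new - lam) <= tol * abs(lam_new):
            return float(lam_new)
        lam = lam_new
    raise RuntimeError("normalization fixed point did not converge")


def contour_area_volume_oracle(
    coefficients: np.ndarray, length: float, n_fine: int = 200001
) -> tuple[float, float]:
    """Reduced area and volume of a tangent-angle contour, brute force.

    Re-evaluates psi(t) = pi t + sum_k a_k sin(k pi t) on a fine uniform
    grid, integrates the radius from the closed top pole downward with plain
    trapezoid sums, and adds the flat contact disc r_c = r(0) contribution.
    Reduced area is A/(4 pi), reduced volume V/(4 pi /3).
    """
    a = np.asarray(coefficients, dtype=float)
    t = np.linspace(0.0, 1.0, n_fine)
    k = np.arange(1, a.size + 1)
    psi = np.pi * t + np.sin(np.pi * np.outer(t, k)) @ a
    cos_psi = np.cos(psi)
    # r(t) = -L * int_t^1 cos psi dt'  (so r(1) = 0 at the top pole)
    h = t[1] - t[0]
    seg = 0.5 * h * (cos_psi[1:] + cos_psi[:-1])
    tail = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    r = -length * tail
    r_c = r[0]
    w = np.full(n_fine, h)
    w[0] = w[-1] = h / 2.0
    area = (2.0 * np.pi * length * np.sum(w * r) + np.pi * r_c**2) / (4.0 * np.pi)
    vol = (np.pi * length * np.sum(w * r**2 * np.sin(psi))) / (4.0 * np.pi / 3.0)
    return float(area), float(vol)
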