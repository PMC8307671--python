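"""Domain types for the electric-double-layer and headgroup models.

All internal quantities are SI; constructors accept the customary
experimental units (mol/L, Debye, nm) and convert at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import DEBYE, E0, EPS0, KB, MOLAR_TO_M3, NM


@dataclass(frozen=True)
class ElectrolyteModel:
    """Bulk electrolyte/water parameters of the Langevin Poisson-Boltzmann model.

    Parameters
    ----------
    n0 : float
        Bulk number density of each monovalent ion species (1/m^3).
    T : float
        Temperature (K).
    nw : float
        Bulk number density of water (1/m^3).
    p0 : float
        Magnitude of the water dipole moment (C*m).
    n_refr : float
        Refractive index of water (electronic polarizability enters as n^2).
    """

    n0: float
    T: float = 298.0
    nw: float = 55.0 * MOLAR_TO_M3
    p0: float = 3.1 * DEBYE
    n_refr: float = 1.33

    def __post_init__(self) -> None:
        if not (self.n0 > 0 and self.nw > 0 and self.T > 0):
            raise ValueError("n0, nw and T must be positive")
        if self.p0 < 0:
            raise ValueError("p0 must be non-negative")
        if self.n_refr < 1:
            raise ValueError("refractive index must be >= 1")

    @classmethod
    def from_molar(
        cls,
        salt_molar: float,
        temperature: float = 298.0,
        water_molar: float = 55.0,
        p0_debye: float = 3.1,
        refractive_index: float = 1.33,
    ) -> "ElectrolyteModel":
        """Build a model from concentrations in mol/L and dipole moment in Debye."""
        return cls(
            n0=salt_molar * MOLAR_TO_M3,
            T=temperature,
            nw=water_molar * MOLAR_TO_M3,
            p0=p0_debye * DEBYE,
            n_refr=refractive_index,
        )

    @property
    def beta(self) -> float:
        """1/kT (1/J)."""
        return 1.0 / (KB * self.T)

    @property
    def kT(self) -> float:
        return KB * self.T

    @property
    def gamma(self) -> float:
        """Cavity-field factor (2 + n^2)/2."""
        return (2.0 + self.n_refr**2) / 2.0

    @property
    def gamma3(self) -> float:
        """(2 + n^2)/3, the cavity/reaction-field prefactor of the dipole terms."""
        return (2.0 + self.n_refr**2) / 3.0

    @property
    def eps_r_bulk(self) -> float:
        """Onsager-limit bulk relative permittivity (zero-field limit)."""
        return (
            self.n_refr**2
            + self.gamma3**2 * self.nw * self.p0**2 * self.beta / (2.0 * EPS0)
        )

    @property
    def debye_length(self) -> float:
        """Debye screening length computed with the bulk permittivity (m)."""
        return np.sqrt(
            EPS0 * self.eps_r_bulk / (2.0 * E0**2 * self.n0 * self.beta)
        )


@dataclass(frozen=True)
class PlanarGap:
    """Two charged planar surfaces: sigma1 at x = 0, sigma2 at x = H."""

    H: float
    sigma1: float
    sigma2: float

    def __post_init__(self) -> None:
        if not self.H > 0:
            raise ValueError("gap width H must be positive")

    @classmethod
    def from_nm(cls, H_nm: float, sigma1: float, sigma2: float) -> "PlanarGap":
        return cls(H=H_nm * NM, sigma1=sigma1, sigma2=sigma2)


@dataclass
class FieldProfile:
    """Discretized solution of the planar LPB boundary-value problem.

    Node arrays live on ``x``; the solver additionally stores the cell
    midpoints (``x_mid``) where the electric field of the conservative
    finite-difference scheme is most accurate, which is what the osmotic
    pressure functionals evaluate.
    """

    x: np.ndarray
    phi: np.ndarray
    E: np.ndarray
    eps_r: np.ndarray
    n_plus: np.ndarray
    n_minus: np.ndarray
    rho: np.ndarray
    converged: bool
    residual: float
    clipped: bool
    gap: PlanarGap
    iterations: int = 0
    x_mid: Optional[np.ndarray] = None
    phi_mid: Optional[np.ndarray] = None
    E_mid: Optional[np.ndarray] = None
    residual_history: Optional[list] = None

    @property
    def H(self) -> float:
        return self.gap.H


@dataclass
class PressureResult:
    """Osmotic pressure between the surfaces relative to the bulk reservoir.

    ``Pi`` is Pi_inner - Pi_bulk (Pa, positive = repulsion), ``K`` the local
    pressure constant (first integral of the planar LPB equation), and
    ``constancy_residual`` the maximum relative pointwise deviation of the
    pressure functional across the evaluation region -- a direct numerical
    check of the contact theorem.
    """

    Pi: float
    K: float
    constancy_residual: float
    method: str
    quality: Optional[float] = None
    pointwise: Optional[np.ndarray] = None
    x_eval: Optional[np.ndarray] = None


@dataclass(frozen=True)
class HeadgroupModel:
    """Zwitterionic headgroup layer facing a charged wall.

    The phosphate (negative) charges sit as a surface charge ``sigma1 < 0``
    at x = 0; the positive trimethylammonium charge of each headgroup is
    distributed over 0 < x <= D with probability density P(x).  ``alpha`` is
    the ratio of headgroup positive-charge volume to salt-solution volume in
    the headgroup region (finite-size partition parameter).  The charged wall
    with ``sigma2`` sits at x = H.
    """

    D: float
    alpha: float
    sigma1: float
    sigma2: float
    H: float

    def __post_init__(self) -> None:
        if not (0 < self.D < self.H):
            raise ValueError("require 0 < D < H")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not self.sigma1 < 0:
            raise ValueError("phosphate-plane charge sigma1 must be negative")

    @classmethod
    def from_nm(
        cls, D_nm: float, alpha: float, sigma1: float, sigma2: float, H_nm: float
    ) -> "HeadgroupModel":
        return cls(D=D_nm * NM, alpha=alpha, sigma1=sigma1, sigma2=sigma2, H=H_nm * NM)

    @property
    def gap(self) -> PlanarGap:
        return PlanarGap(H=self.H, sigma1=self.sigma1, sigma2=self.sigma2)


@dataclass
class HeadgroupProfile:
    """FieldProfile extended with the headgroup charge distribution."""

    base: FieldProfile
    Lambda: float
    P: np.ndarray
    rho_zw: np.ndarray
    mean_x: float
    mean_omega: float
    i_D: int
    model: HeadgroupModel
    outer_iterations: int = 0
    outer_converged: bool = True
    normalization_defect: float = 0.0

    @property
    def converged(self) -> bool:
        return self.base.converged and self.outer_converged
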