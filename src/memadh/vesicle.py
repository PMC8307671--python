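"""Axisymmetric vesicle shapes: Helfrich bending energy plus contact adhesion.

The shape problem is posed in reduced units: lengths are scaled by
Rs = sqrt(A/4pi), so the membrane area is fixed at 4pi (reduced area 1) and
the enclosed volume at (4pi/3) v with v the reduced volume.  The reduced free
energy, in units of the bending energy 8 pi kappa of a sphere, is

    f = (1/4) oint (c1 + c2 - c0)^2 da  -  (w/2) (Ac/A),

with c1, c2 the reduced principal curvatures, c0 the reduced spontaneous
curvature and w = W Rs^2 / kappa the reduced adhesion strength.  The Gaussian
curvature term is a topological constant for the closed vesicles studied here
and is dropped.

Contours are represented by the tangent angle psi along normalized arc
length t in [0, 1]:

    psi(t) = pi t + sum_k a_k sin(k pi t),        s = L t,

which builds in psi(0) = 0 and psi(1) = pi: the contour starts tangent to the
substrate plane (or flat at a free pole) and ends at the upper pole.  The
radial coordinate is integrated from the pole down, r(t) = -L int_t^1 cos psi,
so closure at the top is exact and the residual radius r_c = r(0) is the
radius of the adhered flat disc (zero for a free vesicle, where it is
constrained away).  Up-down symmetric shapes use only even Fourier modes;
odd modes encode pears and all adhered shapes.

Energy, area and volume are trapezoid quadratures over a dense t grid; the
constrained minimization (SLSQP) runs on the Fourier amplitudes plus the
total arc length L with analytic adjoint gradients throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize

__all__ = [
    "ReducedShapeProblem",
    "ShapeContour",
    "ShapeResult",
    "geometry_from_angle",
    "reduced_energy",
    "minimize_shape",
    "classify_shape",
    "find_transition",
    "adhesion_scan",
    "reduced_adhesion",
    "seed_shape",
    "trace_branch",
]

_Q_FLOOR = 1e-10        # below this reduced radius a node counts as a pole
_NEG_PENALTY = 1.0e3    # soft barrier against r < 0 during iteration


@dataclass(frozen=True)
class ReducedShapeProblem:
    """Reduced shape-energy problem: volume v, spontaneous curvature c0, adhesion w."""

    v: float
    c0: float = 0.0
    w: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.v <= 1.0):
            raise ValueError("reduced volume must be in (0, 1]")
        if self.w < 0:
            raise ValueError("reduced adhesion strength must be >= 0")


@dataclass
class ShapeContour:
    """Discretized axisymmetric contour in reduced units."""

    a: np.ndarray          # Fourier sine amplitudes of psi
    L: float               # total reduced arc length of the free contour
    t: np.ndarray          # normalized arc length grid
    psi: np.ndarray
    r: np.ndarray
    z: np.ndarray
    c1: np.ndarray         # meridional curvature d psi / ds
    c2: np.ndarray         # azimuthal curvature sin psi / r
    r_c: float             # adhered-disc radius (flat contact segment)
    area: float            # reduced area (free part + disc), target 1
    volume: float          # reduced volume, target v

    @property
    def ac_frac(self) -> float:
        """Reduced contact area Ac/A = (pi r_c^2) / (4 pi)."""
        return self.r_c**2 / 4.0

    @property
    def n_modes(self) -> int:
        return self.a.size


@dataclass
class ShapeResult:
    """Converged minimum of the reduced shape energy."""

    contour: ShapeContour
    f: float
    f_bend: float
    ac_frac: float
    shape_class: str
    class_confidence: float
    multipliers: dict
    area_residual: float
    volume_residual: float
    converged: bool
    message: str = ""
    nit: int = 0
    problem: Optional[ReducedShapeProblem] = None

    @property
    def contact_curvature(self) -> float:
        """Meridional curvature of the free contour at the contact line."""
        return float(self.contour.c1[0])


# ---------------------------------------------------------------------------
# forward geometry + adjoint machinery
# ---------------------------------------------------------------------------

def _basis(t: np.ndarray, M: int):
    k = np.arange(1, M + 1)
    S = np.sin(np.pi * np.outer(t, k))          # (N+1, M)
    C = (k * np.pi) * np.cos(np.pi * np.outer(t, k))
    return S, C


def _trap_w(n: int, h: float) -> np.ndarray:
    w = np.full(n, h)
    w[0] = w[-1] = h / 2.0
    return w


def _cumtrap(y: np.ndarray, h: float) -> np.ndarray:
    out = np.empty_like(y)
    out[0] = 0.0
    np.cumsum(0.5 * h * (y[:-1] + y[1:]), out=out[1:])
    return out


def _adjoint_Q(p: np.ndarray, h: float) -> np.ndarray:
    """Transpose of u -> Q, Q_j = int_{t_j}^1 u dt (trapezoid), applied to p."""
    n = p.size
    P = p.sum()
    lam = np.empty(n)
    # reverse exclusive cumulative sum T_i = sum_{j>i} p_j
    T = np.concatenate([np.cumsum(p[::-1])[::-1][1:], [0.0]])
    lam[0] = 0.5 * h * p[0]
    lam[1:-1] = h * (P - T[1:-1] - 0.5 * p[1:-1])
    lam[-1] = 0.5 * h * (P - p[-1])
    return lam


class _ShapeEval:
    """Forward + gradient evaluation of energy and constraints, cached on x."""

    def __init__(self, problem: ReducedShapeProblem, n_modes: int, n_points: int):
        self.pb = problem
        self.M = n_modes
        self.N = n_points
        self.t = np.linspace(0.0, 1.0, n_points + 1)
        self.h = 1.0 / n_points
        self.S, self.C = _basis(self.t, n_modes)
        self.w = _trap_w(n_points + 1, self.h)
        self._x = None
        self._out = None

    # -- forward ---------------------------------------------------------

    def _forward(self, x: np.ndarray) -> dict:
        a, L = x[:-1], x[-1]
        psi = np.pi * self.t + self.S @ a
        d = np.pi + self.C @ a               # d psi / d t
        cpsi, spsi = np.cos(psi), np.sin(psi)
        Q = _cumtrap(-cpsi, self.h)
        Q = Q[-1] - Q                        # int_t^1 (-cos psi)
        return dict(a=a, L=L, psi=psi, d=d, cpsi=cpsi, spsi=spsi, Q=Q)

    def _grad_from_partials(self, fw, pQ, pPsi, pD, pL) -> np.ndarray:
        lam = _adjoint_Q(pQ, self.h)
        gpsi = pPsi + lam * fw["spsi"]
        ga = self.S.T @ gpsi + self.C.T @ pD
        return np.concatenate([ga, [pL]])

    def evaluate(self, x: np.ndarray) -> dict:
        if self._x is not None and np.array_equal(x, self._x):
            return self._out
        fw = self._forward(x)
        pb, w = self.pb, self.w
        L, Q, d, spsi, cpsi = fw["L"], fw["Q"], fw["d"], fw["spsi"], fw["cpsi"]
        c0L = pb.c0 * L
        Q0 = Q[0]
        mask = Q > _Q_FLOOR
        invQ = np.where(mask, 1.0 / np.where(mask, Q, 1.0), 0.0)

        dm = d - c0L
        # bending: (1/8) sum w [ dm^2 Q + 2 dm s + s^2/Q ] + c0^2 r_c^2/16
        T1 = float(w @ (dm**2 * Q))
        T2 = 2.0 * float(w @ (dm * spsi))
        T3 = float(w @ (spsi**2 * invQ))
        f_bend = (T1 + T2 + T3) / 8.0 + pb.c0**2 * (L * Q0) ** 2 / 16.0
        f_adh = -pb.w * (L * Q0) ** 2 / 8.0
        neg = np.minimum(Q, 0.0)
        pen = _NEG_PENALTY * L**2 * float(w @ neg**2)
        J = f_bend + f_adh + pen

        # objective partials
        pQ = w * (dm**2 - spsi**2 * invQ**2) / 8.0 + _NEG_PENALTY * L**2 * w * 2.0 * neg
        pQ[0] += (pb.c0**2 / 8.0 - pb.w / 4.0) * L**2 * Q0
        pPsi = w * cpsi * (dm + spsi * invQ) / 4.0
        pD = w * (dm * Q + spsi) / 4.0
        pL = (
            -(pb.c0 / 4.0) * float(w @ (dm * Q + spsi))
            + (pb.c0**2 / 8.0 - pb.w / 4.0) * L * Q0**2
            + 2.0 * pen / L
        )
        gJ = self._grad_from_partials(fw, pQ, pPsi, pD, pL)

        # area constraint: L^2 (sum w Q)/2 + (L Q0)^2/4 - 1
        IQ = float(w @ Q)
        gA = L**2 * IQ / 2.0 + (L * Q0) ** 2 / 4.0 - 1.0
        pQ_A = L**2 * w / 2.0
        pQ_A = pQ_A.copy()
        pQ_A[0] += L**2 * Q0 / 2.0
        ggA = self._grad_from_partials(
            fw, pQ_A, np.zeros_like(Q), np.zeros_like(Q), L * IQ + L * Q0**2 / 2.0
        )

        # volume constraint: (3/4) L^3 sum w Q^2 s - v
        IV = float(w @ (Q**2 * spsi))
        gV = 0.75 * L**3 * IV - pb.v
        ggV = self._grad_from_partials(
            fw,
            1.5 * L**3 * w * Q * spsi,
            0.75 * L**3 * w * Q**2 * cpsi,
            np.zeros_like(Q),
            2.25 * L**2 * IV,
        )

        # contact-disc radius r_c = L Q0
        gR = L * Q0
        pQ_R = np.zeros_like(Q)
        pQ_R[0] = L
        ggR = self._grad_from_partials(
            fw, pQ_R, np.zeros_like(Q), np.zeros_like(Q), Q0
        )

        out = dict(
            fw=fw, J=J, gJ=gJ, f_bend=f_bend, f_adh=f_adh, pen=pen,
            gA=gA, ggA=ggA, gV=gV, ggV=ggV, gR=gR, ggR=ggR,
        )
        self._x = x.copy()
        self._out = out
        return out


def geometry_from_angle(
    coefficients: np.ndarray,
    length: float,
    n_points: int = 1200,
    check: bool = True,
) -> ShapeContour:
    """Build the contour geometry from Fourier amplitudes and arc length.

    The adhered flat segment is the disc of radius r(0) left by closure; a
    free vesicle has r(0) = 0.  Raises for contours with negative radius.
    """
    a = np.asarray(coefficients, dtype=float)
    if not (np.all(np.isfinite(a)) and np.isfinite(length) and length > 0):
        raise ValueError("coefficients and length must be finite, length > 0")
    t = np.linspace(0.0, 1.0, n_points + 1)
    h = 1.0 / n_points
    S, C = _basis(t, a.size)
    psi = np.pi * t + S @ a
    d = np.pi + C @ a
    cpsi, spsi = np.cos(psi), np.sin(psi)
    cum = _cumtrap(-cpsi, h)
    Q = cum[-1] - cum
    r = length * Q
    if check and np.min(r) < -1e-8 * length:
        raise ValueError(f"invalid contour: negative radius (min r = {np.min(r):.3e})")
    z = length * _cumtrap(spsi, h)
    c1 = d / length
    c2 = np.where(Q > _Q_FLOOR, spsi / np.where(Q > _Q_FLOOR, r, 1.0), c1)
    w = _trap_w(n_points + 1, h)
    r_c = max(float(r[0]), 0.0)
    area = length**2 * float(w @ Q) / 2.0 + r_c**2 / 4.0
    volume = 0.75 * length**3 * float(w @ (Q**2 * spsi))
    return ShapeContour(
        a=a, L=float(length), t=t, psi=psi, r=r, z=z, c1=c1, c2=c2,
        r_c=r_c, area=area, volume=volume,
    )


def reduced_energy(
    contour: ShapeContour, problem: ReducedShapeProblem
) -> tuple[float, float, float]:
    """(f, f_bend, ac_frac) of a contour under the given problem parameters.

    The Lagrange-multiplier constraint terms of the full functional vanish at
    feasible contours and are not included; ``minimize_shape`` reports the
    multiplier estimates separately.
    """
    h = contour.t[1] - contour.t[0]
    w = _trap_w(contour.t.size, h)
    Q = contour.r / contour.L
    mask = Q > _Q_FLOOR
    invQ = np.where(mask, 1.0 / np.where(mask, Q, 1.0), 0.0)
    dm = contour.c1 * contour.L - problem.c0 * contour.L
    spsi = np.sin(contour.psi)
    f_bend = (
        float(w @ (dm**2 * Q + 2.0 * dm * spsi + spsi**2 * invQ)) / 8.0
        + problem.c0**2 * contour.r_c**2 / 16.0
    )
    ac = contour.ac_frac
    return f_bend - problem.w / 2.0 * ac, f_bend, ac


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------

def _fit_profile(psi_target: Callable[[np.ndarray], np.ndarray], M: int) -> np.ndarray:
    """Project psi_target(t) - pi t onto the sine basis."""
    t = np.linspace(0.0, 1.0, 4097)
    y = psi_target(t) - np.pi * t
    k = np.arange(1, M + 1)
    S = np.sin(np.pi * np.outer(t, k))
    return 2.0 * np.trapezoid(S * y[:, None], t, axis=0)


def _two_sphere_radii(v: float) -> tuple[float, float]:
    """Outer/inner radii of the limiting invaginated double sphere at volume v."""

    def defect(r2):
        r1 = np.sqrt(1.0 - r2**2)
        return r1**3 - r2**3 - v

    r2 = brentq(defect, 0.0, np.sqrt(0.5) - 1e-9)
    return float(np.sqrt(1.0 - r2**2)), float(r2)


def seed_shape(name: str, v: float, M: int = 40) -> tuple[np.ndarray, float]:
    """Analytic starting contours (amplitudes, arc length) per shape branch."""
    a = np.zeros(M)
    if name == "sphere":
        return a, np.pi
    if name == "prolate":
        a[1] = 0.45
        return a, np.pi * 1.1
    if name == "oblate":
        a[1] = -0.45
        return a, np.pi * 1.1
    if name == "pear":
        # limiting budded shape: two externally tangent spheres
        # (r1^2 + r2^2 = 1, r1^3 + r2^3 = v) joined by a narrow neck where
        # the tangent angle steps down by pi
        def defect(r2):
            r1 = np.sqrt(1.0 - r2**2)
            return r1**3 + r2**3 - v

        r2 = brentq(defect, 1e-6, np.sqrt(0.5))
        r1 = float(np.sqrt(1.0 - r2**2))
        L = np.pi * (r1 + r2)
        t1 = np.pi * r1 / L
        width = 0.05

        def psi_t(t):
            # tangent-angle slope: pi/t1 on the large sphere, pi/(1-t1) on
            # the bud, with a smoothed -pi turn at the neck
            sig = 0.5 * (1.0 + np.tanh((t - t1) / width))
            slope = (np.pi / t1) * (1.0 - sig) + (np.pi / (1.0 - t1)) * sig
            neck = -np.pi * 0.5 / width / np.cosh((t - t1) / width) ** 2
            dpsi = slope + neck
            psi = np.concatenate(
                [[0.0], np.cumsum(0.5 * (dpsi[1:] + dpsi[:-1]) * np.diff(t))]
            )
            return psi * (np.pi / psi[-1])  # enforce psi(1) = pi exactly

        return _fit_profile(psi_t, M), L
    if name == "stomatocyte":
        r1, r2 = _two_sphere_radii(v)
        L = np.pi * (r1 + r2)
        t1 = np.pi * r1 / L  # fraction of arc on the outer sphere
        width = 0.05

        def psi_t(t):
            # outer sphere turns 0..pi, inner sphere turns back by pi, plus a
            # smoothed +pi neck step at t1 (limiting shape: ends at 2pi -> pi)
            ramp = np.where(
                t < t1,
                t / t1 * np.pi,
                np.pi - (t - t1) / max(1.0 - t1, 1e-9) * np.pi,
            )
            step = np.pi * 0.5 * (1.0 + np.tanh((t - t1) / width))
            return ramp + step

        return _fit_profile(psi_t, M), L
    if name == "pancake":
        rc = np.sqrt(2.0) * 0.95
        eps = max(v * 4.0 / 3.0 / (2.0 * rc**2), 0.02)
        L = np.pi * eps + rc

        def psi_t(t):
            tr = np.pi * eps / L
            return np.where(t < tr, t / tr * np.pi, np.pi)

        return _fit_profile(psi_t, M), L
    raise ValueError(f"unknown seed '{name}'")


def _open_disc(contour: ShapeContour, rho: float, M: int) -> tuple[np.ndarray, float]:
    """Re-seed a contour with a small contact disc of radius ~ rho.

    The bottom cap of the contour below the first radius crossing r = rho is
    cut off and the remaining tangent-angle profile is re-fit; this is the
    nudge off the r_c = 0 critical point (the free shape is always stationary
    against opening a disc, the instability being second order in rho).
    """
    r, t, psi, L = contour.r, contour.t, contour.psi, contour.L
    idx = np.argmax(r >= rho)
    t0 = float(t[max(idx, 1)])
    t0 = min(t0, 0.4)
    psi0 = float(np.interp(t0, t, psi))
    tau = 0.05  # localized flattening toward the contact line

    def psi_new(tt):
        return np.interp(t0 + (1.0 - t0) * tt, t, psi) - psi0 * np.exp(-tt / tau)

    return _fit_profile(psi_new, M), (1.0 - t0) * L


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_shape(contour: ShapeContour, v_hint: Optional[float] = None):
    """Deterministic geometric classification with a confidence score.

    Order of tests: pancake (large contact disc), sphere (uniform curvature),
    stomatocyte (tangent angle overshooting pi: invaginated), then
    prolate/oblate by the height-to-width aspect ratio, with pear as a
    prolate with broken up-down symmetry.
    """
    ac = contour.ac_frac
    if ac > 0.4:
        return "pancake", min(1.0, (ac - 0.4) / 0.1)
    ctot = contour.c1 + contour.c2
    if np.max(np.abs(ctot - 2.0)) < 0.05 and ac < 1e-3:
        return "sphere", 1.0
    over = float(np.max(contour.psi)) - np.pi
    if over > 0.8:
        return "stomatocyte", min(1.0, over / np.pi)
    height = float(np.max(contour.z) - np.min(contour.z))
    width = 2.0 * float(np.max(contour.r))
    aspect = height / width
    conf = min(1.0, abs(aspect - 1.0) / 0.2)
    if aspect <= 1.0:
        return "oblate", conf
    # pear: prolate with significant up-down asymmetry (free shapes only)
    if ac < 1e-3:
        r, rm = contour.r, contour.r[::-1]
        asym = float(np.max(np.abs(r - rm)) / max(np.max(r), 1e-12))
        if asym > 0.15:
            return "pear", min(1.0, asym / 0.3)
    return "prolate", conf


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

def minimize_shape(
    problem: ReducedShapeProblem,
    seed,
    adhered: Optional[bool] = None,
    n_modes: int = 40,
    n_points: int = 1200,
    maxiter: int = 600,
    ftol: float = 1e-12,
) -> ShapeResult:
    """Locally minimize the reduced energy from a seed shape.

    ``seed`` is a branch name ('sphere', 'prolate', 'oblate', 'stomatocyte',
    'pear', 'pancake'), a ShapeContour, or an (amplitudes, L) pair.  With
    ``adhered=False`` the contact-disc radius is constrained to zero (free
    vesicle); with ``adhered=True`` it is kept non-negative and the adhesion
    energy can pull it open.  Default: adhered iff w > 0.
    """
    if adhered is None:
        adhered = problem.w > 0.0
    if isinstance(seed, str):
        a0, L0 = seed_shape(seed, problem.v, M=n_modes)
    elif isinstance(seed, ShapeContour):
        a0, L0 = seed.a, seed.L
    else:
        a0, L0 = seed
    a0 = np.asarray(a0, dtype=float)
    if a0.size < n_modes:
        a0 = np.concatenate([a0, np.zeros(n_modes - a0.size)])
    elif a0.size > n_modes:
        a0 = a0[:n_modes]
    x0 = np.concatenate([a0, [float(L0)]])

    ev = _ShapeEval(problem, n_modes, n_points)

    # scale the objective to O(1) so SLSQP's merit function balances the
    # adhesion energy (which grows like w) against the O(1) constraints
    scale = 1.0 / (1.0 + abs(problem.w))

    def fun(x):
        return scale * ev.evaluate(x)["J"]

    def jac(x):
        return scale * ev.evaluate(x)["gJ"]

    cons = [
        dict(type="eq", fun=lambda x: ev.evaluate(x)["gA"],
             jac=lambda x: ev.evaluate(x)["ggA"]),
        dict(type="eq", fun=lambda x: ev.evaluate(x)["gV"],
             jac=lambda x: ev.evaluate(x)["ggV"]),
    ]
    if adhered:
        cons.append(
            dict(type="ineq", fun=lambda x: ev.evaluate(x)["gR"],
                 jac=lambda x: ev.evaluate(x)["ggR"])
        )
    else:
        cons.append(
            dict(type="eq", fun=lambda x: ev.evaluate(x)["gR"],
                 jac=lambda x: ev.evaluate(x)["ggR"])
        )
    bounds = [(-8.0, 8.0)] * n_modes + [(1.5, 16.0)]
    res = minimize(
        fun, x0, jac=jac, method="SLSQP", constraints=cons, bounds=bounds,
        options=dict(maxiter=maxiter, ftol=ftol),
    )
    if adhered and problem.w > 0:
        # the r_c = 0 shape is stationary against opening a contact disc (the
        # gain and cost are both quadratic in the disc radius), so a gradient
        # method never opens it spontaneously.  Whenever w exceeds a
        # conservative lower bound on the binding threshold (which for a
        # closed shape with pole curvature c1(0) lies near 2 c1(0)^2),
        # restart from a contour with a small disc cut open and keep the
        # lower-energy outcome.
        trial = geometry_from_angle(res.x[:-1], res.x[-1], n_points=n_points,
                                    check=False)
        if trial.r_c < 1e-3:
            # try opening at either pole: the up-down mirror flips the sign
            # of the odd sine modes, a_k -> (-1)^k a_k
            k = np.arange(1, n_modes + 1)
            a_mirror = trial.a * (-1.0) ** k
            mirror = geometry_from_angle(a_mirror, trial.L,
                                         n_points=n_points, check=False)
            for cont in (trial, mirror):
                if problem.w <= 0.5 * cont.c1[0] ** 2:
                    continue
                a_o, L_o = _open_disc(
                    cont, min(0.3, 1.5 / np.sqrt(2 * problem.w)), n_modes)
                x1 = np.concatenate([a_o, [L_o]])
                res2 = minimize(
                    fun, x1, jac=jac, method="SLSQP", constraints=cons,
                    bounds=bounds, options=dict(maxiter=maxiter, ftol=ftol),
                )
                if (res2.success
                        and ev.evaluate(res2.x)["J"] < ev.evaluate(res.x)["J"]):
                    res = res2
    out = ev.evaluate(res.x)
    contour = geometry_from_angle(res.x[:-1], res.x[-1], n_points=n_points, check=False)
    f, f_bend, ac = reduced_energy(contour, problem)
    area_res = abs(out["gA"])
    vol_res = abs(out["gV"])
    ok = bool(res.success) and area_res < 1e-6 and vol_res < 1e-5

    # multiplier estimates: least squares on stationarity grad J + p grad gV
    # + sigma grad gA (+ mu grad r_c for an active contact constraint)
    cols = [out["ggV"], out["ggA"]]
    names = ["p", "sigma"]
    if (not adhered) or out["gR"] <= 1e-8:  # contact constraint active
        cols.append(out["ggR"])
        names.append("mu_contact")
    Amat = np.column_stack(cols)
    mults, *_ = np.linalg.lstsq(Amat, -out["gJ"], rcond=None)
    multipliers = dict(zip(names, (float(m) for m in mults)))

    label, conf = classify_shape(contour, v_hint=problem.v)
    return ShapeResult(
        contour=contour,
        f=f,
        f_bend=f_bend,
        ac_frac=ac,
        shape_class=label,
        class_confidence=conf,
        multipliers=multipliers,
        area_residual=area_res,
        volume_residual=vol_res,
        converged=ok,
        message=res.message,
        nit=res.nit,
        problem=problem,
    )


def trace_branch(
    branch: str,
    v_values: Sequence[float],
    c0: float = 0.0,
    w: float = 0.0,
    n_modes: int = 40,
    n_points: int = 1200,
    anchor_v: Optional[float] = None,
) -> dict:
    """Follow one shape branch over reduced volumes by continuation.

    Returns {v: ShapeResult}.  The branch is anchored at a volume where its
    analytic seed converges robustly and walked toward each requested v.
    """
    anchors = dict(prolate=0.90, oblate=0.85, stomatocyte=0.50, pancake=0.30,
                   pear=0.80, sphere=1.0)
    v0 = anchor_v if anchor_v is not None else anchors[branch]
    results: dict = {}
    res = minimize_shape(
        ReducedShapeProblem(v=v0, c0=c0, w=w), branch,
        n_modes=n_modes, n_points=n_points, adhered=(w > 0),
    )
    results[round(v0, 6)] = res

    def walk(targets: Iterable[float], start_res: ShapeResult, start_v: float):
        cur, cv = start_res, start_v
        for vt in targets:
            # step in increments of at most 0.02
            while abs(vt - cv) > 1e-12:
                step = np.clip(vt - cv, -0.02, 0.02)
                cv = vt if abs(vt - cv) <= 0.02 else cv + step
                cur = minimize_shape(
                    ReducedShapeProblem(v=float(cv), c0=c0, w=w), cur.contour,
                    n_modes=n_modes, n_points=n_points, adhered=(w > 0),
                )
            results[round(float(vt), 6)] = cur

    vs = sorted(set(round(float(v), 6) for v in v_values))
    walk([v for v in vs if v <= v0][::-1], res, v0)
    walk([v for v in vs if v > v0], res, v0)
    return {v: results[v] for v in vs}


class _BranchFollower:
    """Energy of one branch as a function of v, seeded from the nearest solve."""

    def __init__(self, branch, c0, w, n_modes, n_points, anchor_v=None):
        self.branch, self.c0, self.w = branch, c0, w
        self.n_modes, self.n_points = n_modes, n_points
        self.cache: dict = {}
        anchors = dict(prolate=0.90, oblate=0.85, stomatocyte=0.50)
        v0 = anchor_v if anchor_v is not None else anchors[branch]
        res = minimize_shape(
            ReducedShapeProblem(v=v0, c0=c0, w=w), branch,
            n_modes=n_modes, n_points=n_points, adhered=(w > 0),
        )
        self.cache[v0] = res

    def result(self, v: float) -> ShapeResult:
        v = float(v)
        if v in self.cache:
            return self.cache[v]
        vs = np.array(sorted(self.cache))
        v_near = float(vs[np.argmin(np.abs(vs - v))])
        cur, cv = self.cache[v_near], v_near
        while abs(v - cv) > 1e-12:
            cv = v if abs(v - cv) <= 0.02 else cv + np.clip(v - cv, -0.02, 0.02)
            cur = minimize_shape(
                ReducedShapeProblem(v=float(cv), c0=self.c0, w=self.w),
                cur.contour, n_modes=self.n_modes, n_points=self.n_points,
                adhered=(self.w > 0),
            )
            self.cache[float(cv)] = cur
        return cur

    def energy(self, v: float) -> float:
        return self.result(v).f


def find_transition(
    c0: float,
    w: float,
    branch_pair: tuple[str, str],
    v_window: tuple[float, float],
    tol: float = 5.0e-4,
    n_modes: int = 40,
    n_points: int = 1200,
) -> dict:
    """Locate the reduced volume where two shape branches exchange stability.

    Bisects the branch-energy difference f_A(v) - f_B(v) over the window to
    |dv| <= tol; raises if the difference does not change sign, reporting the
    endpoint energies.
    """
    bA = _BranchFollower(branch_pair[0], c0, w, n_modes, n_points)
    bB = _BranchFollower(branch_pair[1], c0, w, n_modes, n_points)
    lo, hi = float(v_window[0]), float(v_window[1])

    def diff(v):
        return bA.energy(v) - bB.energy(v)

    d_lo, d_hi = diff(lo), diff(hi)
    if np.sign(d_lo) == np.sign(d_hi):
        raise ValueError(
            f"no branch crossing in window {v_window}: "
            f"f_{branch_pair[0]} - f_{branch_pair[1]} = {d_lo:.6g} at v={lo}, "
            f"{d_hi:.6g} at v={hi}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        d_mid = diff(mid)
        if np.sign(d_mid) == np.sign(d_lo):
            lo, d_lo = mid, d_mid
        else:
            hi, d_hi = mid, d_mid
    v_star = 0.5 * (lo + hi)
    return dict(
        v_star=v_star,
        bracket=(lo, hi),
        f_A=bA.energy(v_star),
        f_B=bB.energy(v_star),
        branch_pair=branch_pair,
        results_A=bA.cache,
        results_B=bB.cache,
    )


def adhesion_scan(
    v: float,
    c0: float,
    w_list: Sequence[float],
    seed_policy: str = "continuation",
    seed: Optional[str] = None,
    n_modes: int = 40,
    n_points: int = 1200,
) -> list:
    """Family of adhered minima along ascending reduced adhesion strengths.

    Starts from the free minimum (or a named seed branch) and continues in w;
    per-point failures are recorded (ShapeResult with converged=False) and the
    scan continues from the last good shape.
    """
    w_list = list(w_list)
    if any(np.diff(w_list) < 0):
        raise ValueError("w_list must be ascending")
    if seed is None:
        candidates = [
            minimize_shape(
                ReducedShapeProblem(v=v, c0=c0, w=0.0), br,
                n_modes=n_modes, n_points=n_points, adhered=False,
            )
            for br in ("prolate", "oblate", "stomatocyte")
        ]
        good = [r for r in candidates if r.converged] or candidates
        free = min(good, key=lambda r: r.f)
    else:
        free = minimize_shape(
            ReducedShapeProblem(v=v, c0=c0, w=0.0), seed,
            n_modes=n_modes, n_points=n_points, adhered=False,
        )
    out = []
    cur = free
    for wv in w_list:
        res = minimize_shape(
            ReducedShapeProblem(v=v, c0=c0, w=float(wv)), cur.contour,
            n_modes=n_modes, n_points=n_points, adhered=wv > 0,
        )
        out.append(res)
        if res.converged:
            cur = res
    return out


def reduced_adhesion(W: float, Rs: float, kappa: float) -> float:
    """Reduced adhesion strength w = W Rs^2 / kappa."""
    if not (kappa > 0 and Rs > 0):
        raise ValueError("Rs and kappa must be positive")
    return W * Rs**2 / kappa
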