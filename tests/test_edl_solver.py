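"""Boundary-value solver and osmotic-pressure functional tests."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memadh import edl, oracles
from memadh.constants import EPS0
from memadh.models import ElectrolyteModel, PlanarGap

from conftest import FAST_NODES, FULL_NODES


def _electroneutrality(profile):
    """Relative defect of sigma1 + sigma2 + int rho dx (cell quadrature)."""
    g = profile.gap
    x = profile.x
    w = np.zeros_like(x)
    h = np.diff(x)
    w[0] = h[0] / 2
    w[-1] = h[-1] / 2
    w[1:-1] = (h[:-1] + h[1:]) / 2
    total = g.sigma1 + g.sigma2 + float(np.sum(w * profile.rho))
    scale = max(abs(g.sigma1), abs(g.sigma2), 1e-12)
    return abs(total) / scale


class TestSolvePlanar:
    def test_uncharged_trivial(self, water_010m):
        prof = edl.solve_planar_edl(
            PlanarGap.from_nm(4.0, 0.0, 0.0), water_010m, n_nodes=FAST_NODES)
        assert np.max(np.abs(prof.phi)) < 1e-12
        assert np.max(prof.E) < 1e-6
        assert edl.osmotic_pressure_profile(prof, water_010m).Pi == pytest.approx(
            0.0, abs=1e-9)

    def test_antisymmetric_midplane_zero(self, water_010m):
        prof = edl.solve_planar_edl(
            PlanarGap.from_nm(4.0, 0.2, -0.2), water_010m, n_nodes=FAST_NODES)
        phi_mid = float(np.interp(prof.H / 2, prof.x, prof.phi))
        assert abs(phi_mid) < 1e-10 * np.max(np.abs(prof.phi))

    def test_electroneutrality(self, water_010m):
        prof = edl.solve_planar_edl(
            PlanarGap.from_nm(4.0, 0.2, -0.1), water_010m, n_nodes=FAST_NODES)
        assert _electroneutrality(prof) < 1e-6

    def test_mirror_symmetry(self, water_010m):
        g1 = PlanarGap.from_nm(4.0, 0.15, -0.05)
        g2 = PlanarGap.from_nm(4.0, -0.05, 0.15)
        p1 = edl.solve_planar_edl(g1, water_010m, n_nodes=FAST_NODES)
        p2 = edl.solve_planar_edl(g2, water_010m, n_nodes=FAST_NODES)
        # reflect p2: phi2(H - x) should equal phi1(x); the grid is symmetric
        assert np.allclose(p1.phi, p2.phi[::-1], rtol=0,
                           atol=1e-12 * np.max(np.abs(p1.phi)))

    def test_permittivity_bounds_on_solution(self, water_010m):
        prof = edl.solve_planar_edl(
            PlanarGap.from_nm(3.0, 0.3, -0.3), water_010m, n_nodes=FAST_NODES)
        assert np.all(prof.eps_r >= water_010m.n_refr**2 - 1e-12)
        assert np.all(prof.eps_r <= water_010m.eps_r_bulk + 1e-12)
        assert np.all(prof.n_plus * prof.n_minus == pytest.approx(
            water_010m.n0**2, rel=1e-9))

    def test_debye_huckel_potential(self, water_010m, weak_gap):
        prof = edl.solve_planar_edl(weak_gap, water_010m, n_nodes=FAST_NODES)
        orc = oracles.debye_huckel_oracle(weak_gap, water_010m)
        phi_o = np.interp(prof.x, orc.x, orc.phi)
        rel = np.max(np.abs(prof.phi - phi_o)) / np.max(np.abs(phi_o))
        assert rel < 0.01

    def test_classical_pb_reduction(self):
        # p0 = 0 collapses the closure to a constant permittivity n^2; the
        # weak-charge solution must then match Debye-Hueckel with eps = n^2.
        # Dilute salt keeps the (much shorter) Debye length resolved, and the
        # tiny charge keeps phi well inside the linear regime.
        m = ElectrolyteModel.from_molar(0.001, p0_debye=0.0)
        assert m.eps_r_bulk == pytest.approx(m.n_refr**2, rel=1e-14)
        weak_gap = PlanarGap.from_nm(6.0, 1e-5, -1e-5)
        prof = edl.solve_planar_edl(weak_gap, m, n_nodes=FAST_NODES)
        assert np.allclose(prof.eps_r, m.n_refr**2, rtol=1e-12)
        orc = oracles.debye_huckel_oracle(weak_gap, m)
        phi_o = np.interp(prof.x, orc.x, orc.phi)
        assert np.max(np.abs(prof.phi - phi_o)) / np.max(np.abs(phi_o)) < 0.01

    def test_input_errors(self, water_010m):
        with pytest.raises(ValueError):
            PlanarGap(H=-1e-9, sigma1=0.0, sigma2=0.0)
        with pytest.raises(ValueError):
            edl.solve_planar_edl(PlanarGap.from_nm(2.0, 0.1, -0.1),
                                 water_010m, n_nodes=2)

    def test_nonconvergence_reports_history(self, water_010m):
        # starved iteration budget must fail loudly, with history attached
        with pytest.raises(RuntimeError, match="residual"):
            edl.solve_planar_edl(PlanarGap.from_nm(2.0, 0.3, -0.3),
                                 water_010m, n_nodes=201, max_iter=1,
                                 ramp_steps=(1.0,))

    @given(
        mag=st.floats(min_value=0.01, max_value=0.25),
        sign=st.sampled_from([-1.0, 1.0]),
        ratio=st.floats(min_value=-1.0, max_value=1.0),
        H_nm=st.floats(min_value=1.0, max_value=8.0),
    )
    @settings(max_examples=12, deadline=None)
    def test_property_bundle(self, mag, sign, ratio, H_nm):
        sigma = mag * sign
        m = ElectrolyteModel.from_molar(0.1)
        prof = edl.solve_planar_edl(
            PlanarGap.from_nm(H_nm, sigma, sigma * ratio), m,
            n_nodes=FAST_NODES)
        assert prof.converged
        assert _electroneutrality(prof) < 1e-6
        assert np.all(prof.eps_r >= m.n_refr**2 - 1e-12)


class TestPressure:
    @pytest.mark.parametrize("salt,H_nm", [(0.01, 1.0), (0.01, 4.0),
                                           (0.15, 1.0), (0.15, 4.0)])
    def test_contact_theorem_constancy(self, salt, H_nm):
        m = ElectrolyteModel.from_molar(salt)
        prof = edl.solve_planar_edl(PlanarGap.from_nm(H_nm, 0.2, -0.2), m)
        pres = edl.osmotic_pressure_profile(prof, m)
        assert pres.constancy_residual < 1e-5

    def test_eq9_equals_eq8(self, water_010m):
        prof = edl.solve_planar_edl(
            PlanarGap.from_nm(4.0, 0.2, -0.2), water_010m, n_nodes=FAST_NODES)
        a = edl.osmotic_pressure_pointwise(prof, water_010m)
        b = edl.osmotic_pressure_pointwise(prof, water_010m, use_densities=True)
        assert np.allclose(a, b, rtol=1e-12)

    def test_midplane_matches_full_for_equal_sigma(self, water_010m):
        prof = edl.solve_planar_edl(
            PlanarGap.from_nm(4.0, 0.1, 0.1), water_010m, n_nodes=None)
        full = edl.osmotic_pressure_profile(prof, water_010m)
        mid = edl.osmotic_pressure_midplane(prof, water_010m)
        assert mid.Pi >= 0.0
        assert mid.Pi == pytest.approx(full.Pi, rel=2e-5)

    def test_midplane_requires_equal_sigma(self, water_010m):
        prof = edl.solve_planar_edl(
            PlanarGap.from_nm(4.0, 0.1, -0.1), water_010m, n_nodes=FAST_NODES)
        with pytest.raises(ValueError):
            edl.osmotic_pressure_midplane(prof, water_010m)

    def test_weakfield_matches_full(self, water_010m, weak_gap):
        prof = edl.solve_planar_edl(weak_gap, water_010m, n_nodes=None)
        full = edl.osmotic_pressure_profile(prof, water_010m)
        wf = edl.osmotic_pressure_weakfield(prof, water_010m)
        assert wf.quality < 0.1
        assert wf.Pi == pytest.approx(full.Pi, rel=0.05)

    def test_weakfield_field_term_value(self, water_010m):
        # -sigma^2/(2 eps0 eps_rb) with sigma = 0.2 As/m^2, eps_rb ~ 78.5
        val = -0.2**2 / (2 * EPS0 * water_010m.eps_r_bulk)
        assert val == pytest.approx(-2.88e7, rel=0.005)

    def test_weakfield_attraction_vs_oracle(self, water_010m, weak_gap):
        prof = edl.solve_planar_edl(weak_gap, water_010m, n_nodes=None)
        Pi = edl.osmotic_pressure_profile(prof, water_010m).Pi
        Pi_dh = oracles.debye_huckel_pressure(weak_gap, water_010m)
        assert Pi < 0.0  # antisymmetric charges attract
        assert Pi == pytest.approx(Pi_dh, rel=0.02)

    def test_refuses_unconverged(self, water_010m):
        prof = edl.solve_planar_edl(
            PlanarGap.from_nm(4.0, 0.05, 0.0), water_010m, n_nodes=FAST_NODES)
        prof.converged = False
        with pytest.raises(ValueError):
            edl.osmotic_pressure_profile(prof, water_010m)


class TestPressureCurve:
    def test_monotone_and_decay(self, water_010m):
        H_list = [h * 1e-9 for h in (1.0, 2.0, 4.0, 8.0, 14.0)]
        tbl = edl.pressure_distance_curve(
            water_010m, 0.2, -0.2, H_list, n_nodes=FAST_NODES)
        assert tbl.converged.all()
        assert tbl.attrs["abs_Pi_increases_as_H_decreases"]
        # screened decoupling: |Pi| at 14 nm (~15 Debye lengths) is tiny
        assert abs(tbl.Pi.iloc[-1]) < 1e-3 * abs(tbl.Pi.iloc[0])
        # antisymmetric charges: attraction throughout
        assert (tbl.Pi < 0).all()
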