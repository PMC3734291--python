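"""Tissue continuum: mechanics, phase kinetics, level set, oxygen, GF."""

import numpy as np
import pytest

from tumorperf import continuum as ct
from tumorperf.grid import Grid, SingularSystemError, cfl_dt_advection
from tumorperf.params import GrowthParams


@pytest.fixture()
def grid():
    return Grid((32, 32), h=30.0)


def _state(grid, params, phi_t=0.0, phi_n=0.4, phi_d=0.0, c=1.0,
           theta_const=1e6):
    return ct.ContinuumState(
        grid, np.full(grid.shape, float(theta_const)),
        np.full(grid.shape, float(phi_t)), np.full(grid.shape, float(phi_n)),
        np.full(grid.shape, float(phi_d)), ecm_fraction=params.ecm_fraction,
        c=np.full(grid.shape, float(c)))


class TestMechanics:
    def test_pressure_zero_at_and_below_relaxed_fraction(self):
        p = GrowthParams()
        phi = np.array([0.0, p.relaxed_cell_fraction, 0.2])
        assert np.all(ct.solid_pressure(phi, p) == 0.0)

    def test_pressure_linear_above_threshold(self):
        p = GrowthParams()
        phi = np.linspace(p.relaxed_cell_fraction, 0.8, 9)
        press = ct.solid_pressure(phi, p)
        slopes = np.diff(press) / np.diff(phi)
        assert np.allclose(slopes, 1.0)

    def test_velocity_zero_for_uniform_pressure(self, grid):
        p = GrowthParams()
        v = ct.cell_velocity(grid, np.full(grid.shape, 0.3), p)
        assert all(np.allclose(f, 0.0) for f in v)

    def test_velocity_constant_for_linear_ramp(self, grid):
        p = GrowthParams()
        x = grid.meshgrid()[0]
        slope = 1e-3
        v = ct.cell_velocity(grid, slope * x, p)
        interior = v[0][1:-1, :]
        assert np.allclose(interior, -p.mobility_modulus * slope)


class TestPhaseSources:
    def test_net_rate_vanishes_at_homeostatic_density(self, grid):
        p = GrowthParams()
        st = _state(grid, p, phi_t=p.homeostatic_tumor_fraction, phi_n=0.0,
                    c=1.0, theta_const=-1e6)
        s_t, _s_n, s_d = ct.phase_sources(st, p)
        assert np.allclose(s_t, 0.0)
        assert np.allclose(s_d, 0.0)
        # the same cancellation holds for normal tissue with its apoptosis
        st2 = _state(grid, p, phi_t=0.0, phi_n=p.homeostatic_normal_fraction)
        _s_t2, s_n2, _ = ct.phase_sources(st2, p)
        assert np.allclose(s_n2, 0.0, atol=1e-15)

    def test_hypoxia_stops_proliferation_and_transfers_mass(self, grid):
        p = GrowthParams()
        st = _state(grid, p, phi_t=0.3, phi_n=0.0,
                    c=0.5 * p.oxygen_necrosis_threshold, theta_const=-1e6)
        s_t, _s_n, s_d = ct.phase_sources(st, p)
        assert np.all(s_t < 0)          # pure loss below the necrosis gate
        assert np.all(s_d > 0)          # transferred, not destroyed

    def test_necrosis_is_internal_transfer(self, grid):
        # d/dt(phi_T + phi_D) carries no necrosis term when apoptosis = 0
        p = GrowthParams()
        st = _state(grid, p, phi_t=0.3, phi_n=0.0,
                    c=0.5 * p.oxygen_necrosis_threshold, theta_const=-1e6)
        s_t, _s_n, s_d = ct.phase_sources(st, p)
        assert np.allclose(s_t + s_d, 0.0, atol=1e-15)

    def test_density_dependence_is_linear_around_homeostasis(self, grid):
        p = GrowthParams()
        # just below the homeostatic fraction the per-cell net rate is
        # k (phi_h - phi) with k = sensitivity * max proliferation rate
        phis = [0.56, 0.57, 0.58, 0.59]
        rates = []
        for phi in phis:
            st = _state(grid, p, phi_t=phi, phi_n=0.0, theta_const=-1e6)
            rates.append(float(ct.phase_sources(st, p)[0][0, 0] / phi))
        slopes = np.diff(rates) / np.diff(phis)
        k = p.pressure_sensitivity * p.prolif_rate_tumor_per_h
        assert np.allclose(slopes, -k, rtol=1e-9)


class TestAdvancePhases:
    def test_stationary_without_velocity_and_sources(self, grid):
        p = GrowthParams()
        st = _state(grid, p, phi_t=0.0, phi_n=p.homeostatic_normal_fraction)
        v = [np.zeros(grid.face_shape(a)) for a in range(2)]
        new = ct.advance_phases(st, v, 0.5, p)
        assert np.allclose(new.phi_N, st.phi_N, atol=1e-12)
        assert np.allclose(new.phi_T, st.phi_T)

    def test_blob_translation_within_scheme_diffusion(self):
        grid = Grid((64, 4), h=30.0)
        p = GrowthParams(prolif_rate_normal_per_h=0.0,
                         apoptosis_rate_normal_per_h=0.0,
                         necrosis_rate_normal_per_h=0.0)
        x = grid.axes()[0]
        blob = 0.3 * np.exp(-((x[:, None] - 500.0) / 220.0) ** 2) * np.ones((1, 4))
        st = ct.ContinuumState(grid, np.full(grid.shape, 1e6), grid.zeros(),
                               blob, grid.zeros(), ecm_fraction=p.ecm_fraction,
                               c=np.ones(grid.shape))
        speed = 10.0   # µm/h
        v = [np.full(grid.face_shape(0), speed), np.zeros(grid.face_shape(1))]
        dt = 0.4 * cfl_dt_advection(grid, v)
        t_total = 30.0
        n = int(round(t_total / dt))
        cur = st
        for _ in range(n):
            cur = ct.advance_phases(cur, v, dt, p)
        shift = speed * dt * n
        exact = 0.3 * np.exp(-((x[:, None] - 500.0 - shift) / 220.0) ** 2)
        l1 = np.mean(np.abs(cur.phi_N - exact)) / np.mean(exact)
        assert l1 < 0.05

    def test_necrotic_mass_monotone_in_hypoxia(self, grid):
        p = GrowthParams()
        st = _state(grid, p, phi_t=0.4, phi_n=0.0, c=0.0, theta_const=-1e6)
        v = [np.zeros(grid.face_shape(a)) for a in range(2)]
        masses = [st.phi_D.sum()]
        cur = st
        for _ in range(30):
            cur = ct.advance_phases(cur, v, 0.5, p)
            masses.append(cur.phi_D.sum())
        assert np.all(np.diff(masses) >= 0)
        assert masses[-1] > masses[0]

    def test_closure_maintained_throughout(self, grid):
        p = GrowthParams()
        st = _state(grid, p, phi_t=0.55, phi_n=0.0, theta_const=-1e6)
        v = [np.zeros(grid.face_shape(a)) for a in range(2)]
        cur = st
        for _ in range(20):
            cur = ct.advance_phases(cur, v, 0.5, p)
            cur.validate_closure()


class TestLevelSet:
    def test_zero_velocity_keeps_contour(self, grid):
        th = ct.sphere_levelset(grid, 300.0)
        v = [np.zeros(grid.face_shape(a)) for a in range(2)]
        out = ct.advect_levelset(grid, th, v, 1.0)
        assert np.allclose(out, th)

    def test_sphere_translation_preserves_radius(self):
        grid = Grid((48, 48), h=30.0)
        th = ct.sphere_levelset(grid, 300.0)
        v = [np.full(grid.face_shape(0), 5.0), np.zeros(grid.face_shape(1))]
        cur = th.copy()
        for _ in range(20):
            cur = ct.advect_levelset(grid, cur, v, 1.0)
        mesh = grid.meshgrid()
        c = np.array([0.5 * 48 * 30.0 + 100.0, 0.5 * 48 * 30.0])
        exact = np.sqrt((mesh[0] - c[0]) ** 2 + (mesh[1] - c[1]) ** 2) - 300.0
        band = np.abs(exact) < 2 * grid.h
        assert np.max(np.abs(cur - exact)[band]) < 0.1 * grid.h

    def test_redistance_restores_gradient_norm(self):
        grid = Grid((48, 48), h=30.0)
        th = ct.sphere_levelset(grid, 300.0)
        mesh = grid.meshgrid()
        distorted = th * np.exp(0.5 * np.sin(mesh[0] / 200.0))
        rd = ct.redistance(grid, distorted)
        gn = ct.gradient_norm(grid, rd)
        ext = (rd > 2 * grid.h) & (rd < 280.0)   # smooth exterior band
        assert np.all((gn[ext] > 0.95) & (gn[ext] < 1.05))
        inn = (rd < -2 * grid.h) & (rd > -150.0)  # interior, off the skeleton
        assert np.all((gn[inn] > 0.9) & (gn[inn] < 1.1))

    def test_redistance_pins_zero_contour(self):
        grid = Grid((48, 48), h=30.0)
        th = ct.sphere_levelset(grid, 300.0)
        mesh = grid.meshgrid()
        distorted = th * np.exp(0.5 * np.sin(mesh[0] / 200.0))
        rd = ct.redistance(grid, distorted)
        band = np.abs(th) < 1.5 * grid.h
        assert np.max(np.abs(rd - th)[band]) < 0.1 * grid.h


class TestOxygen:
    def test_no_vessels_no_consumption_is_singular(self, grid, params):
        from tumorperf.sampling import SurfaceSampling
        st = _state(grid, params.growth, phi_n=0.0)
        empty = SurfaceSampling(
            grid, np.zeros((0, 2)), np.zeros(0), np.zeros(0),
            np.zeros(0, int), [], np.zeros(0), np.zeros(0),
            np.zeros(0, bool), np.zeros(0, bool))
        p0 = GrowthParams(oxygen_cons_normal=0.0, oxygen_cons_tumor=0.0,
                          oxygen_cons_necrotic=0.0)
        with pytest.raises(SingularSystemError):
            ct.oxygen_field(st, empty, p0)

    def test_no_vessels_with_consumption_gives_zero(self, grid, params):
        from tumorperf.sampling import SurfaceSampling
        st = _state(grid, params.growth)
        empty = SurfaceSampling(
            grid, np.zeros((0, 2)), np.zeros(0), np.zeros(0),
            np.zeros(0, int), [], np.zeros(0), np.zeros(0),
            np.zeros(0, bool), np.zeros(0, bool))
        c = ct.oxygen_field(st, empty, params.growth)
        assert np.allclose(c, 0.0)

    def test_slab_decay_matches_closed_form(self, params):
        # perfused vessel plane at one side, uniform consumption:
        # c ~ exp(-x / sqrt(D_eff/alpha)) in the far field
        from tumorperf.fixtures import make_fixture
        from tumorperf.rng import named_stream
        from tumorperf.sampling import sample_surfaces
        from scipy.optimize import curve_fit
        net, st = make_fixture("single-vessel-block", size=32, params=params)
        samp = sample_surfaces(net, st.grid, named_stream(0, "ox"))
        c = ct.oxygen_field(st, samp, params.growth)
        # plane source + uniform consumption + far Neumann wall:
        # c(y) = A cosh((L - y)/ell) with ell = 1/sqrt(alpha/D)
        alpha = params.growth.oxygen_cons_normal * 0.4
        ell = 1.0 / np.sqrt(alpha)
        prof = c.mean(axis=0)
        yy = st.grid.axes()[1]
        j_v = int(np.argmax(prof))
        top = 32 * st.grid.h
        sel = slice(j_v + 2, 32)
        popt, _ = curve_fit(lambda y, a, el: a * np.cosh((top - y) / el),
                            yy[sel], prof[sel], p0=[0.01, 300.0])
        assert abs(popt[1]) == pytest.approx(ell, rel=0.02)

    def test_unperfused_vessels_give_no_oxygen(self, grid, params):
        from tumorperf.fixtures import make_fixture
        from tumorperf.rng import named_stream
        from tumorperf.sampling import sample_surfaces
        net, st = make_fixture("single-vessel-block", size=32, params=params)
        for _a, _b, d in net.graph.edges(data=True):
            d["perfused"] = False
        samp = sample_surfaces(net, st.grid, named_stream(0, "ox"))
        c = ct.oxygen_field(st, samp, params.growth)
        assert np.allclose(c, 0.0)

    def test_bounded_between_zero_and_one(self, params):
        from tumorperf.fixtures import make_fixture
        from tumorperf.rng import named_stream
        from tumorperf.sampling import sample_surfaces
        net, st = make_fixture("frozen-spherical-tumor", size=24, params=params)
        samp = sample_surfaces(net, st.grid, named_stream(0, "ox"))
        c = ct.oxygen_field(st, samp, params.growth)
        assert c.min() >= 0.0 and c.max() <= 1.0


class TestGrowthFactor:
    def test_no_hypoxic_sites_gives_zero(self, grid, params):
        st = _state(grid, params.growth, phi_t=0.5, phi_n=0.0, c=1.0)
        assert np.allclose(ct.growth_factor_field(st, params.growth), 0.0)

    def test_single_source_cutoff_radius(self, params):
        grid = Grid((40, 40), h=30.0)
        p = params.growth
        st = _state(grid, p, phi_t=0.0, phi_n=0.0, c=1.0)
        st.phi_T[20, 20] = 0.5
        st.c[20, 20] = 0.0
        g = ct.growth_factor_field(st, p)
        mesh = grid.meshgrid()
        c0 = np.array([mesh[0][20, 20], mesh[1][20, 20]])
        d = np.sqrt((mesh[0] - c0[0]) ** 2 + (mesh[1] - c0[1]) ** 2)
        assert np.all(g[d >= p.gf_radius + grid.h] < 1e-12)
        assert g[20, 20] == pytest.approx(1.0)
        near = (d > 0) & (d < p.gf_radius - grid.h)
        assert np.all(g[near] > 0.0)

    def test_overlapping_sources_capped_at_one(self, params):
        grid = Grid((30, 30), h=30.0)
        p = params.growth
        st = _state(grid, p, phi_t=0.5, phi_n=0.0, c=0.0)
        g = ct.growth_factor_field(st, p)   # every cell a source
        assert g.max() <= 1.0
        assert g.min() >= 0.99   # saturated everywhere
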