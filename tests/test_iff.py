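"""Interstitial fluid pressure/flow: Starling sources, lymph sinks, Darcy."""

import numpy as np
import pytest

from tumorperf import iff
from tumorperf.continuum import ContinuumState
from tumorperf.fixtures import make_fixture
from tumorperf.grid import Grid, divergence
from tumorperf.hemodynamics import normal_wall_thickness, solve_nodal_pressures
from tumorperf.params import IFParams, Parameters
from tumorperf.rng import named_stream
from tumorperf.sampling import sample_surfaces


@pytest.fixture(scope="module")
def frozen():
    params = Parameters()
    net, state = make_fixture("frozen-spherical-tumor", size=32, seed=1,
                              params=params)
    samp = sample_surfaces(net, state.grid, named_stream(1, "ifp"))
    sol = iff.assemble_and_solve_ifp(state, samp, params.iff)
    src = iff.source_decomposition(state, samp, sol, params.iff)
    return params, net, state, samp, sol, src


class TestWallPermeability:
    def test_anchored_at_normal_thickness(self):
        p = IFParams()
        for r in (4.0, 10.0, 30.0):
            w = float(normal_wall_thickness(r))
            assert iff.wall_hydraulic_permeability(w, r, p) == pytest.approx(
                p.wall_perm_normal)

    def test_capped_for_degenerate_wall(self):
        p = IFParams()
        assert iff.wall_hydraulic_permeability(0.0, 10.0, p) == p.wall_perm_tumor
        assert iff.wall_hydraulic_permeability(1e-6, 10.0, p) == p.wall_perm_tumor

    def test_monotone_non_increasing_in_thickness(self):
        p = IFParams()
        w = np.linspace(0.0, 10.0, 50)
        lam = iff.wall_hydraulic_permeability(w, 10.0, p)
        assert np.all(np.diff(lam) <= 1e-15)


class TestIFPSolve:
    def test_equilibrium_blood_pressure_gives_flat_field(self, params):
        # p_blood = p* + sigma dpi everywhere, no lymphatics, anchored at
        # p* -> constant pressure, zero flow
        net, state = make_fixture("single-vessel-block", size=16, params=params)
        p = IFParams(lymph_surface_density=0.0)
        target = 1.5
        dpi = p.oncotic_vessel - p.oncotic_interstitial
        for s in net.graph.nodes:
            net.graph.nodes[s]["press"] = target + p.reflection_normal * dpi
        samp = sample_surfaces(net, state.grid, named_stream(0, "eq"))
        mask = np.zeros(state.grid.shape, bool)
        mask[0, :] = True
        sol = iff.assemble_and_solve_ifp(state, samp, p, dirichlet_mask=mask,
                                         dirichlet_values=target)
        assert np.allclose(sol.pressure, target, atol=1e-8)
        assert all(np.allclose(u, 0.0, atol=1e-10) for u in sol.velocity)

    def test_lymphatic_screening_length(self, params):
        # homogeneous slab with lymphatics only, boundary pinned high:
        # decay exp(-x/sqrt(K/(lambda_L S_L)))
        _net, state = make_fixture("homogeneous-lymphatic-slab", size=64,
                                   params=params)
        p = params.iff
        grid = state.grid
        from tumorperf.sampling import SurfaceSampling
        empty = SurfaceSampling(grid, np.zeros((0, 2)), np.zeros(0),
                                np.zeros(0), np.zeros(0, int), [], np.zeros(0),
                                np.zeros(0), np.zeros(0, bool),
                                np.zeros(0, bool))
        mask = np.zeros(grid.shape, bool)
        mask[0, :] = True
        sol = iff.assemble_and_solve_ifp(state, empty, p, dirichlet_mask=mask,
                                         dirichlet_values=2.0)
        kappa = p.lymph_wall_perm * p.lymph_surface_density
        kcond = p.conductivity_normal
        ell = np.sqrt(kcond / kappa)
        x = grid.axes()[0]
        prof = sol.pressure[:, grid.shape[1] // 2] - p.lymph_pressure
        sel = slice(4, 32)
        pred = prof[4] * np.exp(-(x[sel] - x[4]) / ell)
        assert np.allclose(prof[sel], pred, rtol=2e-2)

    def test_singular_without_any_sink(self, params):
        _net, state = make_fixture("homogeneous-lymphatic-slab", size=16,
                                   params=params)
        p = IFParams(lymph_surface_density=0.0)
        from tumorperf.grid import SingularSystemError
        from tumorperf.sampling import SurfaceSampling
        empty = SurfaceSampling(state.grid, np.zeros((0, 2)), np.zeros(0),
                                np.zeros(0), np.zeros(0, int), [], np.zeros(0),
                                np.zeros(0), np.zeros(0, bool),
                                np.zeros(0, bool))
        with pytest.raises(SingularSystemError):
            iff.assemble_and_solve_ifp(state, empty, p)

    def test_tumor_ifp_elevated_with_boundary_drop(self, frozen):
        _p, _net, state, _samp, sol, _src = frozen
        tumor_core = state.theta < -100.0
        far = state.theta > 300.0
        assert sol.pressure[tumor_core].mean() > sol.pressure[far].mean() + 0.3
        # profile drops across the boundary: rim mean between core and far
        rim = np.abs(state.theta) < 60.0
        assert (sol.pressure[tumor_core].mean() > sol.pressure[rim].mean()
                > sol.pressure[far].mean())


class TestDarcyAndSources:
    def test_velocity_zero_for_uniform_pressure(self):
        grid = Grid((12, 12), h=30.0)
        u = iff.darcy_velocity(grid, np.full(grid.shape, 2.0),
                               np.full(grid.shape, 6.4))
        assert all(np.allclose(f, 0.0) for f in u)

    def test_velocity_constant_for_linear_ramp(self):
        grid = Grid((12, 12), h=30.0)
        x = grid.meshgrid()[0]
        slope = 1e-3
        u = iff.darcy_velocity(grid, slope * x, np.full(grid.shape, 6.4))
        assert np.allclose(u[0][1:-1, :], -6.4 * slope)

    def test_divergence_matches_sources_cellwise(self, frozen):
        _p, _net, state, _samp, sol, _src = frozen
        scale = np.abs(iff.exact_net_source(sol)).max()
        assert iff.conservation_residual(state.grid, sol) < 1e-8 * scale

    def test_source_field_invariants(self, frozen):
        _p, _net, state, _samp, _sol, src = frozen
        assert np.all(src.vessel_in >= 0)
        assert np.all(src.vessel_out >= 0)
        assert np.all(src.lymph_out >= 0)
        assert np.allclose(src.total,
                           src.vessel_in - src.vessel_out - src.lymph_out)

    def test_no_lymphatic_uptake_deep_inside_tumor(self, frozen):
        _p, _net, state, _samp, _sol, src = frozen
        interior = state.theta < -2 * state.grid.h
        assert np.all(src.lymph_out[interior] == 0.0)

    def test_some_tumor_vessels_absorb_fluid(self, frozen):
        _p, _net, state, _samp, _sol, src = frozen
        assert src.vessel_out[state.tumor_mask()].sum() > 0.0

    def test_global_budget_closes(self, frozen):
        # with zero-flux outer boundaries the integrated net source is zero
        _p, _net, state, _samp, sol, src = frozen
        vol = state.grid.cell_volume
        net_total = src.total.sum() * vol
        influx = src.vessel_in.sum() * vol
        assert abs(net_total) < 1e-6 * influx

    def test_linearity_in_driving_pressures(self, params):
        # scaling blood, lymphatic and osmotic pressures by s scales p and u
        net, state = make_fixture("single-vessel-block", size=16,
                                  params=params)
        samp = sample_surfaces(net, state.grid, named_stream(3, "lin"))
        p1 = params.iff
        sol1 = iff.assemble_and_solve_ifp(state, samp, p1)
        s = 2.5
        import dataclasses
        p2 = dataclasses.replace(p1, lymph_pressure=s * p1.lymph_pressure,
                                 oncotic_vessel=s * p1.oncotic_vessel,
                                 oncotic_interstitial=s * p1.oncotic_interstitial)
        samp2 = sample_surfaces(net, state.grid, named_stream(3, "lin"))
        samp2.blood_pressure = s * samp2.blood_pressure
        sol2 = iff.assemble_and_solve_ifp(state, samp2, p2)
        assert np.allclose(sol2.pressure, s * sol1.pressure, rtol=1e-8)
        for u1, u2 in zip(sol1.velocity, sol2.velocity):
            assert np.allclose(u2, s * u1, rtol=1e-8, atol=1e-12)

    def test_influx_monotone_in_wall_permeability(self, params):
        import dataclasses
        net, state = make_fixture("frozen-spherical-tumor", size=24, seed=4,
                                  params=params)
        samp = sample_surfaces(net, state.grid, named_stream(4, "mono"))
        influx = []
        for scale in (0.3, 1.0, 3.0):
            p = dataclasses.replace(params.iff,
                                    wall_perm_tumor=scale * params.iff.wall_perm_tumor)
            sol = iff.assemble_and_solve_ifp(state, samp, p)
            src = iff.source_decomposition(state, samp, sol, p)
            influx.append(src.vessel_in[state.tumor_mask()].sum())
        assert influx[0] < influx[1] < influx[2]

    def test_influx_drops_with_lower_tissue_conductivity(self, params):
        import dataclasses
        net, state = make_fixture("frozen-spherical-tumor", size=24, seed=4,
                                  params=params)
        samp = sample_surfaces(net, state.grid, named_stream(4, "mono"))
        influx = []
        for scale in (0.05, 1.0):
            p = dataclasses.replace(
                params.iff,
                conductivity_normal=scale * params.iff.conductivity_normal,
                conductivity_tumor=scale * params.iff.conductivity_tumor,
                conductivity_necrotic=scale * params.iff.conductivity_necrotic)
            sol = iff.assemble_and_solve_ifp(state, samp, p)
            src = iff.source_decomposition(state, samp, sol, p)
            influx.append(src.vessel_in[state.tumor_mask()].sum())
        assert influx[0] < influx[1]


class TestDecayLengthAndExtravasation:
    def test_sealed_wall_recovers_poiseuille(self):
        assert iff.vessel_pressure_decay_length(10.0, 4e-6, 0.0) == np.inf

    def test_square_root_scaling(self):
        l1 = iff.vessel_pressure_decay_length(10.0, 4e-6, 1e-3)
        l4 = iff.vessel_pressure_decay_length(10.0, 4e-6, 4e-3)
        assert l1 == pytest.approx(2 * l4)

    def test_against_ode_shooting_oracle(self):
        # leaky-pipe two-point boundary problem integrated numerically:
        # p'' = (p - p_inf)/lambda^2; the numeric profile must match
        # A exp(x/l) + B exp(-x/l) with the analytic decay length
        from scipy.integrate import solve_ivp
        r, eta, lam_w = 8.0, 4e-6, 2e-3
        lam = iff.vessel_pressure_decay_length(r, eta, lam_w)
        kax = np.pi * r ** 4 / (8 * eta)
        wall = lam_w * 2 * np.pi * r
        length = 3 * lam

        def rhs(_x, y):
            return [y[1], (wall / kax) * y[0]]

        # shoot to satisfy p(0)=1, p(L)=0.2 (relative to interstitial level)
        def boundary_mismatch(s):
            sol = solve_ivp(rhs, (0, length), [1.0, s], rtol=1e-10,
                            atol=1e-12, dense_output=True)
            return sol, sol.y[0, -1] - 0.2

        lo, hi = -1.0, 1.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            _, miss = boundary_mismatch(mid)
            if miss > 0:
                hi = mid
            else:
                lo = mid
        sol, _ = boundary_mismatch(0.5 * (lo + hi))
        x = np.linspace(0, length, 50)
        num = sol.sol(x)[0]
        # fit A, B of the closed form and compare profiles
        basis = np.vstack([np.exp(x / lam), np.exp(-x / lam)]).T
        coef, *_ = np.linalg.lstsq(basis, num, rcond=None)
        assert np.allclose(basis @ coef, num, atol=1e-6 * np.abs(num).max())

    def test_sealed_walls_zero_ratio(self, params):
        import dataclasses
        net, state = make_fixture("frozen-spherical-tumor", size=24, seed=2,
                                  params=params)
        p = dataclasses.replace(params.iff, wall_perm_tumor=0.0,
                                wall_perm_normal=0.0)
        samp = sample_surfaces(net, state.grid, named_stream(2, "rg"))
        sol = iff.assemble_and_solve_ifp(state, samp, p)
        src = iff.source_decomposition(state, samp, sol, p)
        flow = solve_nodal_pressures(net)
        assert iff.extravasation_ratio(state, net, flow, src) == 0.0

    def test_ratio_is_small_and_positive_on_fixture(self, frozen):
        _p, net, state, _samp, _sol, src = frozen
        flow = solve_nodal_pressures(net)
        r_gamma = iff.extravasation_ratio(state, net, flow, src)
        assert 0.0 < r_gamma < 1e-2

    def test_empty_tumor_errors(self, params):
        net, state = make_fixture("single-vessel-block", size=16,
                                  params=params)
        samp = sample_surfaces(net, state.grid, named_stream(0, "e"))
        sol = iff.assemble_and_solve_ifp(state, samp, params.iff)
        src = iff.source_decomposition(state, samp, sol, params.iff)
        flow = solve_nodal_pressures(net)
        with pytest.raises(ValueError):
            iff.extravasation_ratio(state, net, flow, src)
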