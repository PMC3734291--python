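"""Continuum tissue state and dynamics.

Tissue is a mixture of tumor cells, normal cells, necrotic debris, a
fixed ECM fraction and interstitial fluid; the fractions close to one
pointwise (the fluid fraction is the remainder).  All cellular phases
share one velocity, driven by the gradient of a solid pressure through a
porous-medium (Darcy-like) mobility.  The tumor-host interface is a
signed-distance level set (negative inside the tumor).  Oxygen is a
quasi-stationary diffusion-consumption field sourced by perfused vessel
surfaces and normalized to 1 in blood; the growth factor is a
superposition of linearly decaying kernels around hypoxic tumor sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .grid import (Grid, advect, cfl_dt_advection, divergence, elliptic_solve,
                   gradient_faces)
from .params import GrowthParams
from .sampling import SurfaceSampling


# --------------------------------------------------------------------------
# state
# --------------------------------------------------------------------------

@dataclass
class ContinuumState:
    grid: Grid
    theta: np.ndarray            # signed distance, < 0 inside the tumor (µm)
    phi_T: np.ndarray
    phi_N: np.ndarray
    phi_D: np.ndarray
    ecm_fraction: float = 0.2
    c: np.ndarray = None         # oxygen, normalized to blood level 1
    g: np.ndarray = None         # growth factor, normalized <= 1

    def __post_init__(self):
        if self.c is None:
            self.c = self.grid.zeros()
        if self.g is None:
            self.g = self.grid.zeros()

    @property
    def phi_cells(self) -> np.ndarray:
        return self.phi_T + self.phi_N + self.phi_D

    @property
    def phi_f(self) -> np.ndarray:
        """Interstitial-fluid fraction: the closure remainder."""
        return 1.0 - self.ecm_fraction - self.phi_cells

    def validate_closure(self, tol: float = 1e-9) -> None:
        for name in ("phi_T", "phi_N", "phi_D"):
            a = getattr(self, name)
            if np.any(a < -tol) or np.any(a > 1 + tol):
                raise AssertionError(f"{name} escaped [0, 1]")
        pf = self.phi_f
        if np.any(pf < -tol) or np.any(pf > 1 + tol):
            raise AssertionError("fluid fraction escaped [0, 1]: closure violated")

    def tumor_mask(self) -> np.ndarray:
        return self.theta < 0.0


def sphere_levelset(grid: Grid, radius: float,
                    center: np.ndarray | None = None) -> np.ndarray:
    """Signed distance to a sphere (negative inside)."""
    mesh = grid.meshgrid()
    if center is None:
        center = np.array([grid.origin[a] + 0.5 * grid.shape[a] * grid.h
                           for a in range(grid.ndim)])
    r = np.sqrt(sum((m - c) ** 2 for m, c in zip(mesh, center)))
    return r - radius


def smoothed_heaviside(x: np.ndarray, width: float) -> np.ndarray:
    """C1 smoothed step of half-width ``width`` (grid spacing by default)."""
    xi = np.clip(x / width, -1.0, 1.0)
    return np.clip(0.5 * (1.0 + xi + np.sin(np.pi * xi) / np.pi), 0.0, 1.0)


# --------------------------------------------------------------------------
# mechanics
# --------------------------------------------------------------------------

def solid_pressure(phi: np.ndarray, params: GrowthParams) -> np.ndarray:
    """Linear-elastic solid pressure, zero below the relaxed fraction.

    Returned in units of the elastic modulus; the combined parameter
    mobility*modulus converts its gradient to a velocity.
    """
    return np.maximum(phi - params.relaxed_cell_fraction, 0.0)


def cell_velocity(grid: Grid, pressure: np.ndarray,
                  params: GrowthParams) -> list[np.ndarray]:
    """Face-centered tissue velocity v = -(mobility*modulus) grad p, µm/h."""
    g = gradient_faces(grid, pressure)
    return [-params.mobility_modulus * gi for gi in g]


# --------------------------------------------------------------------------
# sources
# --------------------------------------------------------------------------

def phase_sources(state: ContinuumState,
                  params: GrowthParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Net production rates (1/h) for tumor, normal and necrotic phases.

    Proliferation is gated on oxygen above the proliferation threshold and
    regulated by packing density: the rate is min(max rate,
    apoptosis + sensitivity*max_rate*(phi_h - phi)), so that at the
    homeostatic fraction proliferation and apoptosis cancel and the net
    rate varies linearly with the total cell fraction around it.
    Necrosis below the necrosis threshold transfers mass to the necrotic
    phase; apoptosis removes mass without debris.
    """
    phi = state.phi_cells
    c = state.c
    prol_gate = (c > params.oxygen_prolif_threshold).astype(float)
    necro_gate = (c < params.oxygen_necrosis_threshold).astype(float)

    def net_pa(phi_x, r_p, r_a, phi_h):
        k = params.pressure_sensitivity * r_p
        prolif = np.minimum(r_p, np.maximum(r_a + k * (phi_h - phi), 0.0))
        return phi_x * (prolif * prol_gate - r_a)

    s_T = net_pa(state.phi_T, params.prolif_rate_tumor_per_h,
                 params.apoptosis_rate_tumor_per_h,
                 params.homeostatic_tumor_fraction)
    s_N = net_pa(state.phi_N, params.prolif_rate_normal_per_h,
                 params.apoptosis_rate_normal_per_h,
                 params.homeostatic_normal_fraction)
    necro_T = params.necrosis_rate_tumor_per_h * state.phi_T * necro_gate
    necro_N = params.necrosis_rate_normal_per_h * state.phi_N * necro_gate
    s_T = s_T - necro_T
    s_N = s_N - necro_N
    s_D = necro_T + necro_N
    return s_T, s_N, s_D


def split_viable(phi_v: np.ndarray, theta: np.ndarray,
                 width: float) -> tuple[np.ndarray, np.ndarray]:
    """Partition the viable cell fraction into tumor/normal via theta.

    Tumor and normal cells are immiscible, separated by the level-set
    interface: the split is phi_v * (1 - H(theta)) inside and
    phi_v * H(theta) outside, with a smoothed Heaviside of width the
    grid spacing.
    """
    h_out = smoothed_heaviside(theta, width)
    return phi_v * (1.0 - h_out), phi_v * h_out


def stable_dt_phases(state: ContinuumState, v_faces: list[np.ndarray],
                     params: GrowthParams, safety: float = 0.45) -> float:
    """Stable phase step (h): advective CFL and porous-medium limit.

    v = -mobility*modulus grad(phi - phi0)+ makes the transport a
    degenerate nonlinear diffusion with effective coefficient
    mobility*modulus*phi, which carries the stricter h^2 limit.
    """
    grid = state.grid
    dt_adv = cfl_dt_advection(grid, v_faces)
    phi_max = float(np.max(state.phi_cells))
    d_eff = params.mobility_modulus * max(phi_max, 1e-6)
    dt_diff = grid.h ** 2 / (2.0 * grid.ndim * d_eff)
    return safety * min(dt_adv, dt_diff)


def advance_phases(state: ContinuumState, v_faces: list[np.ndarray],
                   dt_h: float, params: GrowthParams) -> ContinuumState:
    """Heun step of the phase transport-reaction system (dt in hours).

    The viable fraction (tumor + normal) and the necrotic fraction are
    advected conservatively; the tumor/normal split is re-derived from
    the level set after the step, which keeps the volume closure intact
    across the moving interface.
    """
    grid = state.grid
    dtmax = cfl_dt_advection(grid, v_faces)
    if dt_h > dtmax * (1 + 1e-12):
        raise ValueError(f"phase advection CFL violated: dt={dt_h:g} > {dtmax:g}")
    from .grid import advective_flux

    def rhs(phi_v, phi_d):
        phi_t, phi_n = split_viable(phi_v, state.theta, grid.h)
        st = ContinuumState(grid, state.theta, phi_t, phi_n, phi_d,
                            state.ecm_fraction, state.c, state.g)
        s_T, s_N, s_D = phase_sources(st, params)
        dv = -divergence(grid, advective_flux(grid, v_faces, phi_v)) + s_T + s_N
        dd = -divergence(grid, advective_flux(grid, v_faces, phi_d)) + s_D
        return dv, dd

    phi_v0 = state.phi_T + state.phi_N
    phi_d0 = state.phi_D
    k1v, k1d = rhs(phi_v0, phi_d0)
    k2v, k2d = rhs(phi_v0 + dt_h * k1v, phi_d0 + dt_h * k1d)
    phi_v = np.maximum(phi_v0 + 0.5 * dt_h * (k1v + k2v), 0.0)
    phi_d = np.maximum(phi_d0 + 0.5 * dt_h * (k1d + k2d), 0.0)
    phi_t, phi_n = split_viable(phi_v, state.theta, grid.h)
    new = ContinuumState(grid, state.theta, phi_t, phi_n, phi_d,
                         state.ecm_fraction, state.c, state.g)
    new.validate_closure(tol=1e-6)
    return new


# --------------------------------------------------------------------------
# level set
# --------------------------------------------------------------------------

def advect_levelset(grid: Grid, theta: np.ndarray, v_faces: list[np.ndarray],
                    dt: float) -> np.ndarray:
    """Non-conservative upwind advection of the level set."""
    dtmax = cfl_dt_advection(grid, v_faces)
    if dt > dtmax * (1 + 1e-12):
        raise ValueError("level-set CFL violated")

    def _mm(a, b):
        return np.where(a * b > 0, np.where(np.abs(a) < np.abs(b), a, b), 0.0)

    def rhs(th):
        # second-order ENO upwind gradients
        out = np.zeros_like(th)
        for ax in range(grid.ndim):
            pad = [(0, 0)] * grid.ndim
            pad[ax] = (2, 2)
            tg = np.pad(th, pad, mode="edge")

            def sl(o_lo, o_hi):
                s = [slice(None)] * grid.ndim
                s[ax] = slice(o_lo, o_hi)
                return tuple(s)

            d1 = (tg[sl(1, None)] - tg[sl(None, -1)]) / grid.h   # first diffs
            d2 = (d1[sl(1, None)] - d1[sl(None, -1)]) / grid.h   # second diffs
            # cell i corresponds to padded index i+2; d1 index k = diff at k-1/2
            dm = d1[sl(1, -2)] + 0.5 * grid.h * _mm(d2[sl(None, -2)], d2[sl(1, -1)])
            dp = d1[sl(2, -1)] - 0.5 * grid.h * _mm(d2[sl(1, -1)], d2[sl(2, None)])
            lo = [slice(None)] * grid.ndim
            hi = [slice(None)] * grid.ndim
            lo[ax] = slice(None, -1)
            hi[ax] = slice(1, None)
            u = 0.5 * (v_faces[ax][tuple(lo)] + v_faces[ax][tuple(hi)])
            out -= np.where(u > 0, u * dm, u * dp)
        return out

    k1 = rhs(theta)
    k2 = rhs(theta + dt * k1)
    return theta + 0.5 * dt * (k1 + k2)


def redistance(grid: Grid, theta: np.ndarray, iterations: int | None = None,
               cfl: float = 0.3) -> np.ndarray:
    """Restore |grad theta| = 1 while pinning the zero contour.

    PDE reinitialization with a Godunov Hamiltonian and the subcell
    (interface-locked) correction of Russo & Smereka in cells whose stencil
    straddles the interface, so the zero contour moves by far less than a
    cell during reinitialization.
    """
    h = grid.h
    th0 = theta.copy()
    if iterations is None:
        # enough pseudo-time for the unit-speed correction to sweep the box
        iterations = int(1.2 * max(grid.shape) / cfl)
    sgn = th0 / np.sqrt(th0 ** 2 + h ** 2)

    # interface cells: a sign change with any axis neighbor
    interface = np.zeros(grid.shape, dtype=bool)
    for ax in range(grid.ndim):
        pad = [(0, 0)] * grid.ndim
        pad[ax] = (1, 1)
        tg = np.pad(th0, pad, mode="edge")
        s = [slice(None)] * grid.ndim
        s[ax] = slice(None, -2)
        left = tg[tuple(s)]
        s[ax] = slice(2, None)
        right = tg[tuple(s)]
        interface |= (th0 * left < 0) | (th0 * right < 0)

    # subcell target distance: theta0 scaled by its local gradient magnitude
    grad0_sq = np.zeros(grid.shape)
    for ax in range(grid.ndim):
        pad = [(0, 0)] * grid.ndim
        pad[ax] = (1, 1)
        tg = np.pad(th0, pad, mode="edge")
        s_lo = [slice(None)] * grid.ndim
        s_lo[ax] = slice(None, -2)
        s_hi = [slice(None)] * grid.ndim
        s_hi[ax] = slice(2, None)
        grad0_sq += ((tg[tuple(s_hi)] - tg[tuple(s_lo)]) / (2 * h)) ** 2
    dist0 = th0 / np.maximum(np.sqrt(grad0_sq), 1e-12)

    dt = cfl * h
    th = theta.copy()
    for _ in range(iterations):
        grad_sq = np.zeros(grid.shape)
        for ax in range(grid.ndim):
            pad = [(0, 0)] * grid.ndim
            pad[ax] = (1, 1)
            tg = np.pad(th, pad, mode="edge")
            s_c = [slice(None)] * grid.ndim
            s_c[ax] = slice(1, -1)
            s_m = [slice(None)] * grid.ndim
            s_m[ax] = slice(None, -2)
            s_p = [slice(None)] * grid.ndim
            s_p[ax] = slice(2, None)
            dm = (tg[tuple(s_c)] - tg[tuple(s_m)]) / h
            dp = (tg[tuple(s_p)] - tg[tuple(s_c)]) / h
            gpos = np.maximum(np.maximum(dm, 0.0) ** 2, np.minimum(dp, 0.0) ** 2)
            gneg = np.maximum(np.minimum(dm, 0.0) ** 2, np.maximum(dp, 0.0) ** 2)
            grad_sq += np.where(th0 >= 0, gpos, gneg)
        upd = th - dt * sgn * (np.sqrt(grad_sq) - 1.0)
        # interface cells relax directly toward their subcell distance
        upd_if = th - (dt / h) * (np.sign(th0) * np.abs(th) - dist0)
        th = np.where(interface, upd_if, upd)
    return th


def gradient_norm(grid: Grid, theta: np.ndarray) -> np.ndarray:
    """Central-difference |grad theta| (edges one-sided)."""
    grads = np.gradient(theta, grid.h)
    if grid.ndim == 1:
        grads = [grads]
    return np.sqrt(sum(g ** 2 for g in grads))


# --------------------------------------------------------------------------
# oxygen and growth factor
# --------------------------------------------------------------------------

def oxygen_field(state: ContinuumState, sampling: SurfaceSampling,
                 params: GrowthParams) -> np.ndarray:
    """Stationary diffusion-consumption oxygen field, normalized to 1.

    Solves div(grad c) - (alpha/D) c + (gamma/D) S (c_B - c) = 0 with
    c_B = 1 on perfused vessel surfaces; unperfused vessels contribute
    nothing.  Raises if the system has neither sources nor consumption.
    """
    grid = state.grid
    cons = (params.oxygen_cons_tumor * state.phi_T
            + params.oxygen_cons_normal * state.phi_N
            + params.oxygen_cons_necrotic * state.phi_D)
    s_perf = sampling.surface_density(mask=sampling.perfused.astype(float))
    wall = params.oxygen_wall_perm * s_perf
    if not (np.any(wall > 0) or np.any(cons > 0)):
        from .grid import SingularSystemError
        raise SingularSystemError("oxygen system has no vessel sources and no consumption")
    if not np.any(wall > 0):
        return grid.zeros()
    c = elliptic_solve(grid, np.ones(grid.shape),
                       absorption=cons + wall, source=wall * 1.0)
    return np.clip(c, 0.0, 1.0)


def linear_kernel(grid: Grid, radius: float) -> np.ndarray:
    """Linearly decaying kernel max(0, 1 - d/R) on the grid stencil."""
    n = int(np.ceil(radius / grid.h))
    ax = [np.arange(-n, n + 1) * grid.h for _ in range(grid.ndim)]
    mesh = np.meshgrid(*ax, indexing="ij")
    d = np.sqrt(sum(m ** 2 for m in mesh))
    return np.clip(1.0 - d / radius, 0.0, None)


def growth_factor_field(state: ContinuumState, params: GrowthParams,
                        hypoxia_threshold: float | None = None,
                        phi_threshold: float = 0.01) -> np.ndarray:
    """Growth factor as capped superposition of linear kernels.

    Source sites are cells holding tumor cells whose oxygen level lies
    below the hypoxia threshold (the proliferation-arrest level by
    default); each contributes a linearly decaying bump of radius R_g,
    normalized so a single source peaks at 1; the sum is capped at 1.
    """
    if hypoxia_threshold is None:
        hypoxia_threshold = params.oxygen_prolif_threshold
    src = ((state.phi_T > phi_threshold)
           & (state.c < hypoxia_threshold)).astype(float)
    if not np.any(src > 0):
        return state.grid.zeros()
    kern = linear_kernel(state.grid, params.gf_radius)
    g = signal.fftconvolve(src, kern, mode="same")
    return np.clip(g, 0.0, 1.0)


def distance_to_tumor(grid: Grid, theta: np.ndarray) -> np.ndarray:
    return theta  # theta *is* the signed distance once redistanced


def vessel_tumor_flags(net, theta_interp) -> None:
    """Tag segments as tumor when at least one endpoint is inside (theta<0)."""
    for a, b, d in net.graph.edges(data=True):
        pa = net.lattice.position(a)
        pb = net.lattice.position(b)
        d["tumor"] = bool(theta_interp(pa) < 0.0 or theta_interp(pb) < 0.0)


def make_theta_interpolator(grid: Grid, theta: np.ndarray):
    """Nearest/linear interpolator of theta at arbitrary positions (µm)."""
    from scipy.interpolate import RegularGridInterpolator
    interp = RegularGridInterpolator(
        tuple(grid.axes()), theta, bounds_error=False, fill_value=None)
    return lambda p: float(interp(np.asarray(p, float)[None, :])[0])
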