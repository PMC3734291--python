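"""Two-compartment drug transport on a frozen tumor + IFF state.

The extracellular concentration s1 (per interstitial-fluid volume) is
advected by the interstitial flux, diffuses, exchanges with vessels
(diffusive wall term plus convective extravasation/uptake) and with
lymphatics (pure uptake), and crosses the cell membrane into the
intracellular compartment s2 (per cell volume).  The uptake/release
velocity ratio k12/k21 (= 100 for the Doxorubicin-like base case) sets
the steady intracellular enrichment; exposure is summarized per cell by
the maximum-over-time and the time-integral of s2 (ICmax, ICAUC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .continuum import ContinuumState
from .grid import (Grid, advective_flux, cfl_dt_advection, cfl_dt_diffusion,
                   divergence, face_harmonic, gradient_faces)
from .hemodynamics import normal_wall_thickness
from .iff import IFPSolution, SourceField
from .params import DrugParams
from .sampling import SurfaceSampling


# --------------------------------------------------------------------------
# injection schedules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InjectionSchedule:
    """Blood plasma concentration program, normalized to s_B(0) = 1."""

    mode: str = "bolus"          # "bolus" | "infusion"
    tau_h: float = 1.0           # bolus decay time (h)
    duration_h: float = 24.0     # infusion length (h)

    def __post_init__(self):
        if self.mode not in ("bolus", "infusion"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.tau_h <= 0 or self.duration_h <= 0:
            raise ValueError("schedule time scales must be positive")


def plasma_concentration(t_h: float | np.ndarray,
                         schedule: InjectionSchedule) -> np.ndarray:
    """s_B(t): exp(-t/tau) for a bolus, a unit plateau for an infusion."""
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if schedule.mode == "bolus":
        return np.exp(-t / schedule.tau_h)
    return np.where(t <= schedule.duration_h, 1.0, 0.0)


# --------------------------------------------------------------------------
# exchange terms
# --------------------------------------------------------------------------

def exchange_rate(s1: np.ndarray, s2: np.ndarray, phi_c: np.ndarray,
                  params: DrugParams) -> np.ndarray:
    """Transmembrane flux Gamma_12 = gamma(phi_c) (k12 s1 - k21 s2), 1/s units.

    gamma is the wetted cell-surface area per tissue volume; the flux
    vanishes exactly at the steady ratio s2/s1 = k12/k21.
    """
    gamma = params.gamma(np.asarray(phi_c, float))
    return gamma * (params.k12 * np.asarray(s1) - params.k21 * np.asarray(s2))


def diffusive_wall_permeability(w, r, params: DrugParams) -> np.ndarray:
    """Drug permeability of the vessel wall (µm/s), maturity-interpolated.

    Same form as the hydraulic law: resistance proportional to wall
    thickness, anchored at the normal-capillary value for a
    physiologically normal wall and capped at the leaky tumor value.
    """
    w = np.asarray(w, dtype=float)
    wn = normal_wall_thickness(np.asarray(r, dtype=float))
    with np.errstate(divide="ignore"):
        lam = np.where(w > 0, params.wall_perm_normal * wn / np.maximum(w, 1e-30),
                       np.inf)
    return np.minimum(lam, params.wall_perm_tumor)


# --------------------------------------------------------------------------
# time stepping
# --------------------------------------------------------------------------

@dataclass
class DrugState:
    grid: Grid
    s1: np.ndarray               # extracellular, per IF volume
    s2: np.ndarray               # intracellular, per cell volume
    t_h: float = 0.0

    def tissue_average(self, phi_f: np.ndarray, phi_c: np.ndarray) -> np.ndarray:
        return phi_f * self.s1 + phi_c * self.s2


@dataclass
class DrugOperators:
    """Precomputed frozen-state coefficient fields for the drug stepper."""

    grid: Grid
    phi_f: np.ndarray
    phi_c: np.ndarray
    u_faces: list[np.ndarray]          # IF volume flux on faces (µm/s)
    diff_faces: list[np.ndarray]       # phi_f-weighted diffusivity on faces
    wall_diff: np.ndarray              # lambda_diff S_v per cell (1/s), perfused only
    conv_in: np.ndarray                # Q_in^v per cell (1/s): carries s_B
    conv_out: np.ndarray               # Q_out^v per cell (1/s): removes s1
    lymph_out: np.ndarray              # Q_out^L per cell (1/s): removes s1
    params: DrugParams
    convection: bool = True


def build_operators(state: ContinuumState, sampling: SurfaceSampling,
                    ifp: IFPSolution, sources: SourceField,
                    params: DrugParams, convection: bool = True) -> DrugOperators:
    grid = state.grid
    lam = diffusive_wall_permeability(sampling.wall_w, sampling.radius, params)
    wall = sampling.deposit(lam * sampling.perfused.astype(float))
    dfaces = face_harmonic(grid, params.diffusivity * np.clip(state.phi_f, 0.0, None))
    u = ifp.velocity if convection else [np.zeros_like(f) for f in ifp.velocity]
    return DrugOperators(
        grid, np.clip(state.phi_f, 1e-6, None), np.clip(state.phi_cells, 0.0, None),
        u, dfaces, wall, sources.vessel_in.copy(), sources.vessel_out.copy(),
        sources.lymph_out.copy(), params, convection)


def stable_dt_s(ops: DrugOperators, safety: float = 0.7) -> float:
    """Stable sub-step (s) from a per-cell advective+diffusive rate bound.

    The conserved density is m = phi_f s1 while fluxes are built from
    s1 = m/phi_f, so the effective transport rates carry a 1/phi_f
    factor; the bound sums the advective and diffusive face rates per
    cell.  Membrane and vascular exchange are advanced by exact
    exponential relaxations (unconditionally stable) and only an
    accuracy cap applies to them.
    """
    grid = ops.grid
    rate = np.zeros(grid.shape)
    h = grid.h
    for a in range(grid.ndim):
        lo = [slice(None)] * grid.ndim
        hi = [slice(None)] * grid.ndim
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        rate += (np.abs(ops.u_faces[a][tuple(lo)])
                 + np.abs(ops.u_faces[a][tuple(hi)])) / (2.0 * h)
        rate += (ops.diff_faces[a][tuple(lo)]
                 + ops.diff_faces[a][tuple(hi)]) / h ** 2
    rate /= ops.phi_f
    dts = [1.0 / float(np.max(rate))] if np.max(rate) > 0 else []
    gmax = float(np.max(ops.params.gamma(ops.phi_c))) if ops.phi_c.size else 0.0
    if gmax > 0:
        dts.append(2.0 / (gmax * max(ops.params.k12, ops.params.k21)))
    if not dts:
        raise RuntimeError("no finite stable time step")
    dt = safety * min(dts)
    if not np.isfinite(dt) or dt <= 0:
        raise RuntimeError("no finite stable time step")
    return dt


def drug_step(ds: DrugState, ops: DrugOperators, s_blood: float,
              dt_s: float) -> DrugState:
    """One operator-split sub-step (dt in seconds).

    (a) conservative advection of phi_f s1 by the IF flux (central-upwind
    MUSCL, Heun); (b) diffusion of s1 with phi_f-weighted coefficient;
    (c) transmembrane exchange; (d) vascular/lymphatic exchange: diffusive
    wall term toward s_B, convective extravasation carrying s_B, fluid
    uptake removing s1.
    """
    grid = ops.grid
    m1 = ops.phi_f * ds.s1       # conserved extracellular density

    def transport_rhs(m):
        s1 = m / ops.phi_f
        out = np.zeros_like(m)
        if ops.convection:
            out -= divergence(grid, advective_flux(grid, ops.u_faces, s1))
        g = gradient_faces(grid, s1)
        out += divergence(grid, [ops.diff_faces[a] * g[a]
                                 for a in range(grid.ndim)])
        return out

    k1 = transport_rhs(m1)
    k2 = transport_rhs(m1 + dt_s * k1)
    m1 = m1 + 0.5 * dt_s * (k1 + k2)
    s1 = m1 / ops.phi_f
    s2 = ds.s2.copy()

    # (c) transmembrane exchange, exact for the local linear 2x2 system
    gamma = ops.params.gamma(ops.phi_c)
    a = gamma * ops.params.k12 / ops.phi_f
    b = gamma * ops.params.k21 / np.maximum(ops.phi_c, 1e-12)
    lam = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.where(lam > 0, (1.0 - np.exp(-lam * dt_s)) / np.maximum(lam, 1e-300), dt_s)
    ex = (ops.params.k12 * s1 - ops.params.k21 * s2) * gamma * decay
    s1 = s1 - ex / ops.phi_f
    s2 = s2 + ex / np.maximum(ops.phi_c, 1e-12)
    s2 = np.where(ops.phi_c > 0, s2, 0.0)

    # (d) vascular + lymphatic exchange: exact exponential relaxation of the
    # locally linear ds1/dt = (A - B s1)/phi_f (stable and positive)
    b_rate = (ops.wall_diff + ops.conv_out + ops.lymph_out) / ops.phi_f
    a_rate = (ops.wall_diff + ops.conv_in) * s_blood / ops.phi_f
    with np.errstate(divide="ignore", invalid="ignore"):
        s_inf = np.where(b_rate > 0, a_rate / np.maximum(b_rate, 1e-300), 0.0)
        decay_v = np.exp(-b_rate * dt_s)
    s1 = np.where(b_rate > 0, s_inf + (s1 - s_inf) * decay_v,
                  s1 + dt_s * a_rate)
    return DrugState(grid, s1, s2, ds.t_h + dt_s / 3600.0)


@dataclass
class ExposureMaps:
    icmax: np.ndarray
    icauc: np.ndarray            # time integral of s2, in hours
    duration_h: float


def exposure_metrics(trajectory: list[tuple[float, np.ndarray]]) -> ExposureMaps:
    """ICmax and ICAUC (trapezoidal) from a recorded (t_h, s2) trajectory."""
    if not trajectory:
        raise ValueError("empty trajectory")
    times = np.array([t for t, _ in trajectory])
    icmax = trajectory[0][1].copy()
    icauc = np.zeros_like(icmax)
    for i in range(1, len(trajectory)):
        icmax = np.maximum(icmax, trajectory[i][1])
        dt = times[i] - times[i - 1]
        icauc += 0.5 * dt * (trajectory[i][1] + trajectory[i - 1][1])
    return ExposureMaps(icmax, icauc, float(times[-1] - times[0]))


def simulate_drug(state: ContinuumState, ops: DrugOperators,
                  schedule: InjectionSchedule, t_end_h: float = 96.0,
                  record_every_h: float = 1.0,
                  mass_audit: bool = False) -> tuple[DrugState, ExposureMaps, dict]:
    """Integrate the drug system over the observation window.

    Returns the final state, the exposure maps and a log with the recorded
    trajectory and (optionally) the global mass audit.
    """
    grid = ops.grid
    ds = DrugState(grid, grid.zeros(), grid.zeros())
    dt_s = stable_dt_s(ops)
    log: dict = {"trajectory": [(0.0, ds.s2.copy())], "mass": []}
    next_rec = record_every_h
    vol = grid.cell_volume
    mass = 0.0
    while ds.t_h < t_end_h - 1e-9:
        dt = min(dt_s, (t_end_h - ds.t_h) * 3600.0)
        sb = float(plasma_concentration(ds.t_h, schedule))
        if mass_audit:
            influx = float(np.sum(ops.wall_diff * np.maximum(sb - ds.s1, 0)) * vol)
        ds = drug_step(ds, ops, sb, dt)
        if mass_audit:
            m = float(np.sum(ops.phi_f * ds.s1 + ops.phi_c * ds.s2) * vol)
            log["mass"].append((ds.t_h, m))
            mass = m
        if ds.t_h >= next_rec - 1e-9:
            log["trajectory"].append((ds.t_h, ds.s2.copy()))
            next_rec += record_every_h
    if log["trajectory"][-1][0] < ds.t_h:
        log["trajectory"].append((ds.t_h, ds.s2.copy()))
    maps = exposure_metrics(log["trajectory"])
    log["final_mass"] = mass
    return ds, maps, log


# --------------------------------------------------------------------------
# analytic diagnostics
# --------------------------------------------------------------------------

def peclet_unit_length(u_mag: np.ndarray, diffusivity: float) -> np.ndarray:
    """Length at which Pe = 1: L = D/|u| per cell; inf where |u| = 0."""
    u = np.asarray(u_mag, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(u > 0, diffusivity / np.maximum(u, 1e-300), np.inf)


def face_speed_magnitude(grid: Grid, u_faces: list[np.ndarray]) -> np.ndarray:
    """Cell-centered |u| from face fluxes (average of adjacent faces)."""
    comps = []
    for a in range(grid.ndim):
        lo = [slice(None)] * grid.ndim
        hi = [slice(None)] * grid.ndim
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        comps.append(0.5 * (u_faces[a][tuple(lo)] + u_faces[a][tuple(hi)]))
    return np.sqrt(sum(c ** 2 for c in comps))


def saturation_time_h(params: DrugParams, distance_um: float = 1000.0) -> float:
    """Retarded-diffusion time for drug to reach a distance (hours).

    With uptake/release in quasi-steady state almost all drug is arrested
    in cells (s2/s1 = k12/k21), so effective transport is slowed by that
    ratio; the diffusion law x^2 = D_eff t with D_eff = D_s/(k12/k21)
    gives t = (k12/k21) x^2 / D_s.
    """
    if distance_um <= 0:
        raise ValueError("distance must be positive")
    t_s = params.retention_ratio * distance_um ** 2 / params.diffusivity
    return t_s / 3600.0


def compartment_ode_steady_ratio(params: DrugParams, phi_f: float = 0.2,
                                 phi_c: float = 0.6, s1_0: float = 1.0,
                                 t_end_s: float | None = None) -> float:
    """Integrate the closed two-compartment exchange ODE to steady state.

    An isolated, well-mixed tissue element exchanges drug only across the
    cell membrane; mass phi_f s1 + phi_c s2 is conserved and the system
    relaxes to s2/s1 = k12/k21.  Returns the ratio reached at t_end.
    """
    from scipy.integrate import solve_ivp
    gamma = params.gamma(phi_c)
    a = gamma * params.k12 / phi_f
    b = gamma * params.k21 / phi_c

    def rhs(_t, y):
        ex = params.k12 * y[0] - params.k21 * y[1]
        return [-gamma * ex / phi_f, gamma * ex / phi_c]

    if t_end_s is None:
        t_end_s = 40.0 / (a + b)     # many relaxation times
    sol = solve_ivp(rhs, (0.0, t_end_s), [s1_0, 0.0], rtol=1e-12, atol=1e-14,
                    method="LSODA")
    s1, s2 = sol.y[:, -1]
    return float(s2 / s1)
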