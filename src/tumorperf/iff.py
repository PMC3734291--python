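"""Stationary interstitial fluid pressure and flow (IFP/IFF).

The interstitium is a porous medium obeying Darcy's law with a tissue-
dependent conductivity; vessels act as Starling sources (filtration
driven by the transmural pressure minus the effective oncotic pressure
difference), lymphatics as distributed sinks absent inside the tumor.
Both exchange terms are linear in the interstitial pressure, so the
stationary state is a single elliptic solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .continuum import ContinuumState, smoothed_heaviside
from .grid import Grid, divergence, elliptic_solve, face_harmonic, gradient_faces
from .hemodynamics import normal_wall_thickness
from .params import IFParams
from .sampling import SurfaceSampling


# --------------------------------------------------------------------------
# coefficients
# --------------------------------------------------------------------------

def wall_hydraulic_permeability(w: np.ndarray | float, r: np.ndarray | float,
                                params: IFParams) -> np.ndarray:
    """Vessel-wall hydraulic permeability lambda_l(w, r) in µm/(kPa s).

    The wall's resistance grows proportionally to its thickness, anchored
    so that the physiologically normal thickness for the radius yields the
    normal-capillary permeability; as the wall degrades (w -> 0) the
    permeability is capped at the leaky tumor value.
    """
    w = np.asarray(w, dtype=float)
    wn = normal_wall_thickness(np.asarray(r, dtype=float))
    with np.errstate(divide="ignore"):
        lam = np.where(w > 0, params.wall_perm_normal * wn / np.maximum(w, 1e-30),
                       np.inf)
    return np.minimum(lam, params.wall_perm_tumor)


def tissue_conductivity(state: ContinuumState, params: IFParams,
                        width: float | None = None) -> np.ndarray:
    """Darcy conductivity field K (µm²/(kPa s)).

    Interpolates between the normal-tissue and tumor values across the
    interface with a smoothed Heaviside of width the grid spacing, and
    blends toward the necrotic value with the local necrotic fraction.
    """
    grid = state.grid
    if width is None:
        width = grid.h
    inside = 1.0 - smoothed_heaviside(state.theta, width)   # 1 in tumor
    k = (params.conductivity_normal * (1 - inside)
         + params.conductivity_tumor * inside)
    cells = np.maximum(state.phi_cells, 1e-12)
    frac_necro = state.phi_D / cells
    return k * (1 - frac_necro) + params.conductivity_necrotic * frac_necro


def lymphatic_density(state: ContinuumState, params: IFParams,
                      width: float | None = None) -> np.ndarray:
    """Lymphatic surface density S_L, ramped across the boundary like K."""
    grid = state.grid
    if width is None:
        width = grid.h
    inside = 1.0 - smoothed_heaviside(state.theta, width)
    return (params.lymph_surface_density * (1 - inside)
            + params.lymph_surface_density_tumor * inside)


def reflection_coefficient(state: ContinuumState, params: IFParams,
                           width: float | None = None) -> np.ndarray:
    if width is None:
        width = state.grid.h
    inside = 1.0 - smoothed_heaviside(state.theta, width)
    return params.reflection_normal * (1 - inside) + params.reflection_tumor * inside


# --------------------------------------------------------------------------
# solve
# --------------------------------------------------------------------------

@dataclass
class IFPSolution:
    pressure: np.ndarray            # p (kPa), cell-centered
    velocity: list[np.ndarray]      # Darcy flux -K grad p on faces (µm/s)
    vessel_coeff: np.ndarray        # lambda_l S_v per cell (1/(kPa s))
    vessel_drive: np.ndarray        # lambda_l S_v (p_v - sigma dpi) per cell (1/s)
    lymph_coeff: np.ndarray         # lambda_L S_L per cell (1/(kPa s))
    lymph_pressure: float


@dataclass
class SourceField:
    """Per-cell decomposition of the fluid source term (all in 1/s)."""

    total: np.ndarray
    vessel_in: np.ndarray     # Q_in^v  >= 0 (extravasation)
    vessel_out: np.ndarray    # Q_out^v >= 0 (uptake by vessels)
    lymph_out: np.ndarray     # Q_out^L >= 0 (uptake by lymphatics)


def assemble_and_solve_ifp(state: ContinuumState, sampling: SurfaceSampling,
                           params: IFParams,
                           conductivity: np.ndarray | None = None,
                           dirichlet_mask: np.ndarray | None = None,
                           dirichlet_values: float | np.ndarray = 0.0,
                           ) -> IFPSolution:
    """Solve div(K grad p) + Q_v(p) + Q_L(p) = 0 for the IFP.

    Vessel sources use per-sample Starling fluxes lambda_l a_s
    (p_blood - p - sigma (pi_v - pi_i)) deposited through the sampling
    kernel; lymphatic sinks are a continuous distribution
    -lambda_L S_L (p - p_L).  Zero-flux outer boundaries; the pressure
    level is anchored by the lymphatics (or a Dirichlet mask).
    """
    grid = state.grid
    if conductivity is None:
        conductivity = tissue_conductivity(state, params)

    lam = wall_hydraulic_permeability(sampling.wall_w, sampling.radius, params)
    sigma = reflection_coefficient(state, params)
    dpi = params.oncotic_vessel - params.oncotic_interstitial
    # per-sample effective driving pressure, sigma interpolated at samples
    sig_s = sampling.interpolate(sigma)
    p_eff = sampling.blood_pressure - sig_s * dpi

    vessel_coeff = sampling.deposit(lam)                 # 1/(kPa s)
    vessel_drive = sampling.deposit(lam * p_eff)         # kPa/(kPa s) = 1/s
    s_l = lymphatic_density(state, params)
    lymph_coeff = params.lymph_wall_perm * s_l

    absorption = vessel_coeff + lymph_coeff
    source = vessel_drive + lymph_coeff * params.lymph_pressure
    p = elliptic_solve(grid, conductivity, absorption=absorption,
                       source=source, dirichlet_mask=dirichlet_mask,
                       dirichlet_values=dirichlet_values)
    vel = darcy_velocity(grid, p, conductivity)
    return IFPSolution(p, vel, vessel_coeff, vessel_drive, lymph_coeff,
                       params.lymph_pressure)


def darcy_velocity(grid: Grid, p: np.ndarray,
                   conductivity: np.ndarray) -> list[np.ndarray]:
    """Face-centered Darcy flux u = -K grad p (µm/s)."""
    kf = face_harmonic(grid, np.broadcast_to(np.asarray(conductivity, float),
                                             grid.shape))
    g = gradient_faces(grid, p)
    return [-kf[a] * g[a] for a in range(grid.ndim)]


def source_decomposition(state: ContinuumState, sampling: SurfaceSampling,
                         sol: IFPSolution, params: IFParams) -> SourceField:
    """Split the fluid exchange by sign and channel (Starling form).

    Per-sample fluxes use the interstitial pressure interpolated with the
    deposition kernel, so the global budget of (in - out) matches the
    solved net exchange exactly; per cell the split is kernel-accurate.
    """
    grid = state.grid
    lam = wall_hydraulic_permeability(sampling.wall_w, sampling.radius, params)
    sigma = reflection_coefficient(state, params)
    dpi = params.oncotic_vessel - params.oncotic_interstitial
    if sampling.n_samples:
        sig_s = sampling.interpolate(sigma)
        p_s = sampling.interpolate(sol.pressure)
        flux = lam * (sampling.blood_pressure - sig_s * dpi - p_s)  # µm/s per area
        q_in = sampling.deposit(np.maximum(flux, 0.0))
        q_outv = sampling.deposit(np.maximum(-flux, 0.0))
    else:
        q_in = grid.zeros()
        q_outv = grid.zeros()
    q_lymph = np.maximum(sol.lymph_coeff * (sol.pressure - sol.lymph_pressure), 0.0)
    total = q_in - q_outv - q_lymph
    return SourceField(total, q_in, q_outv, q_lymph)


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

def vessel_pressure_decay_length(r: float, length_visc: float,
                                 wall_perm: float) -> float:
    """e-folding length (µm) of blood pressure toward the interstitial level.

    lambda = sqrt(axial conductance per unit length / wall conductance per
    unit length) = sqrt((pi r^4 / 8 eta) / (lambda_l 2 pi r)).  A sealed
    wall (wall_perm -> 0) recovers plain Poiseuille flow (lambda -> inf).
    """
    if r <= 0 or length_visc <= 0:
        raise ValueError("radius and viscosity must be positive")
    axial = np.pi * r ** 4 / (8.0 * length_visc)
    wall = wall_perm * 2.0 * np.pi * r
    if wall == 0:
        return np.inf
    return float(np.sqrt(axial / wall))


def extravasation_ratio(state: ContinuumState, net, flow_sol,
                        sources: SourceField) -> float:
    """r_Gamma: tumor interstitial influx over vascular blood inflow.

    The numerator integrates Q_in^v over the tumor region; the denominator
    sums |q| over vessels whose endpoints straddle the interface with flow
    directed into the tumor.
    """
    grid = state.grid
    mask = state.tumor_mask()
    if not np.any(mask):
        raise ValueError("empty tumor region: extravasation ratio undefined")
    influx = float(np.sum(sources.vessel_in[mask]) * grid.cell_volume)  # µm³/s

    from .continuum import make_theta_interpolator
    th = make_theta_interpolator(grid, state.theta)
    blood_in = 0.0
    for a, b, _d in net.segments():
        ta = th(net.lattice.position(a))
        tb = th(net.lattice.position(b))
        if ta * tb >= 0:
            continue
        q = flow_sol.signed_flow[(a, b)] if (a, b) in flow_sol.signed_flow \
            else -flow_sol.signed_flow[(b, a)]
        # q > 0 means flow a -> b; inflow if the downstream endpoint is inside
        if (q > 0 and tb < 0) or (q < 0 and ta < 0):
            blood_in += abs(q)
    if blood_in == 0:
        return np.inf if influx > 0 else 0.0
    return influx / blood_in


def exact_net_source(sol: IFPSolution) -> np.ndarray:
    """Cell-wise net exchange as assembled in the solve (1/s)."""
    return (sol.vessel_drive - sol.vessel_coeff * sol.pressure
            - sol.lymph_coeff * (sol.pressure - sol.lymph_pressure))


def conservation_residual(grid: Grid, sol: IFPSolution) -> float:
    """Max |div u - Q| over cells, a finite-volume conservation audit.

    Holds to solver precision by construction of the elliptic system.
    """
    div_u = divergence(grid, sol.velocity)
    return float(np.max(np.abs(div_u - exact_net_source(sol))))
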