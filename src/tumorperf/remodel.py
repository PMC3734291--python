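"""Stochastic vascular remodeling during tumor growth.

Angiogenic sprouting (initiation toward the growth-factor gradient, tip
migration, tip splitting), wall degeneration inside the tumor, dilation
(circumferential growth) of co-opted vessels, and collapse of degenerate
low-shear vessels.  Rules fire once per 1 h network step in a fixed,
documented order; each rule draws from its own named RNG stream so that
trajectories are replayable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .continuum import (ContinuumState, advance_phases, advect_levelset,
                        cell_velocity, growth_factor_field,
                        make_theta_interpolator, oxygen_field, redistance,
                        solid_pressure)
from .grid import cfl_dt_advection
from .hemodynamics import apply_flow, solve_nodal_pressures
from .lattice import VesselNetwork
from .params import GrowthParams
from .rng import named_stream
from .sampling import sample_surfaces


def _field_at(grid, field, pos):
    return field[grid.cell_index(pos)]


def update_tumor_flags(net: VesselNetwork, state: ContinuumState,
                       dt_h: float) -> None:
    """Tag tumor vessels (an endpoint with theta < 0) and advance clocks."""
    th = make_theta_interpolator(state.grid, state.theta)
    for a, b, d in net.graph.edges(data=True):
        inside = (th(net.lattice.position(a)) < 0.0
                  or th(net.lattice.position(b)) < 0.0)
        d["tumor"] = bool(inside)
        if inside:
            d["time_in_tumor_h"] += dt_h
        if d["sprout"]:
            d["sprout_age_h"] += dt_h


def _distance_to_branchpoint(net: VesselNetwork, site) -> float:
    """Graph distance (µm) from a site to the nearest node of degree != 2."""
    import collections
    if net.graph.degree(site) != 2:
        return 0.0
    spacing = net.lattice.spacing
    seen = {site}
    frontier = collections.deque([(site, 0.0)])
    while frontier:
        s, dist = frontier.popleft()
        for t in net.graph.neighbors(s):
            if t in seen:
                continue
            from .lattice import bond_direction
            _, nb = bond_direction(s, t)
            d2 = dist + nb * spacing
            if net.graph.degree(t) != 2:
                return d2
            seen.add(t)
            frontier.append((t, d2))
    return np.inf


def sprout_initiation(net: VesselNetwork, state: ContinuumState,
                      params: GrowthParams, rng: np.random.Generator,
                      dt_h: float = 1.0) -> list[tuple]:
    """Stochastically attach new sprout segments at vessel sites.

    A site qualifies if the growth factor there is non-zero, it is farther
    than the minimum separation from a branch point, and its vessel has
    not dwelt in the tumor past the sprouting window.  The new segment
    follows the free neighboring lattice edge of maximal growth-factor
    gradient (ties broken uniformly).
    """
    grid = state.grid
    p_fire = min(1.0, params.sprout_rate_per_h * dt_h)
    sites = list(net.graph.nodes)
    rng.shuffle(sites)
    created = []
    for s in sites:
        pos = net.lattice.position(s)
        g_here = _field_at(grid, state.g, pos)
        if g_here <= 0.0:
            continue
        ages = [net.graph.edges[s, t]["time_in_tumor_h"]
                for t in net.graph.neighbors(s)]
        if ages and min(ages) > params.sprout_max_age_h:
            continue
        if _distance_to_branchpoint(net, s) < params.sprout_min_separation:
            continue
        if rng.random() >= p_fire:
            continue
        best, best_g = [], -np.inf
        for t in net.lattice.neighbors(s):
            if net.bond_occupied(s, t):
                continue
            gt = _field_at(grid, state.g, net.lattice.position(t))
            grad = gt - g_here
            if grad > best_g + 1e-15:
                best, best_g = [t], grad
            elif abs(grad - best_g) <= 1e-15:
                best.append(t)
        if not best:
            continue
        t = best[int(rng.integers(len(best)))]
        net.add_segment(s, t, r=params.sprout_radius,
                        w=0.0, sprout=True, sprout_age_h=0.0)
        created.append((s, t))
    return created


def sprout_migration(net: VesselNetwork, state: ContinuumState,
                     params: GrowthParams, rng: np.random.Generator,
                     dt_h: float = 1.0) -> int:
    """Extend sprout tips along their own direction; handle fusion/aging.

    A tip extension appends one lattice edge in the sprout direction (the
    closest free lattice direction).  If the tip meets another vessel the
    sprout may become a conducting branch: conducting sprouts and sprouts
    beyond the maximal age lose the sprout tag.
    """
    p_ext = min(1.0, (params.sprout_speed / net.lattice.spacing) * dt_h)
    events = 0
    sprout_edges = [(a, b, d) for a, b, d in net.graph.edges(data=True)
                    if d["sprout"]]
    rng.shuffle(sprout_edges)
    for a, b, d in sprout_edges:
        if not net.graph.has_edge(a, b):
            continue
        # the tip is a degree-1 endpoint
        tip = None
        root = None
        for x, y in ((a, b), (b, a)):
            if net.graph.degree(x) == 1:
                tip, root = x, y
        if tip is None:
            continue
        if rng.random() >= p_ext:
            continue
        from .lattice import bond_direction
        unit, _ = bond_direction(root, tip)
        target = tuple(c + u for c, u in zip(tip, unit))
        if not net.lattice.valid_site(target) or net.bond_occupied(tip, target):
            continue
        fused = target in net.graph
        net.add_segment(tip, target, r=d["r"], w=0.0, sprout=True,
                        sprout_age_h=d["sprout_age_h"])
        events += 1
        if fused:
            _untag_if_conducting(net, target)
    # age out
    for a, b, d in net.graph.edges(data=True):
        if d["sprout"] and d["sprout_age_h"] > params.sprout_max_age_h:
            d["sprout"] = False
    return events


def _untag_if_conducting(net: VesselNetwork, site) -> None:
    """After a fusion, untag sprout chains that now lie on an A-V path."""
    try:
        sol = solve_nodal_pressures(net)
    except Exception:
        return
    for a, b, d in net.graph.edges(data=True):
        if d["sprout"] and sol.flow[(a, b)] > 1e-9:
            d["sprout"] = False


def degrade_walls(net: VesselNetwork, params: GrowthParams,
                  dt_h: float = 1.0) -> None:
    """w decreases at the degradation rate for tumor vessels, floored at 0."""
    for _a, _b, d in net.graph.edges(data=True):
        if d["tumor"] and not d["sprout"]:
            d["w"] = max(0.0, d["w"] - params.wall_degradation_rate * dt_h)


def dilate_vessels(net: VesselNetwork, state: ContinuumState,
                   params: GrowthParams, dt_h: float = 1.0) -> int:
    """Circumferential growth of co-opted tumor vessels.

    Requires r < r_max, non-zero growth factor averaged over the segment,
    and tumor residence beyond the switch delay.  Sprouts never dilate.
    """
    grid = state.grid
    n = 0
    for a, b, d in net.graph.edges(data=True):
        if d["sprout"] or not d["tumor"]:
            continue
        if d["time_in_tumor_h"] <= params.switch_delay_h:
            continue
        if d["r"] >= params.max_dilation_radius:
            continue
        ga = _field_at(grid, state.g, net.lattice.position(a))
        gb = _field_at(grid, state.g, net.lattice.position(b))
        if 0.5 * (ga + gb) <= 0.0:
            continue
        d["r"] = min(params.max_dilation_radius,
                     d["r"] + params.dilation_rate * dt_h)
        n += 1
    return n


def maybe_collapse(net: VesselNetwork, params: GrowthParams,
                   rng: np.random.Generator, dt_h: float = 1.0,
                   w_threshold: float = 1e-9) -> list[tuple]:
    """Remove degenerate low-shear vessels stochastically.

    Eligibility: wall stability exhausted (w ~ 0) and wall shear stress
    below the critical value; the removal probability per step is
    min(1, dt / unstable-survival-time).  Sprouts are exempt.
    """
    p = min(1.0, dt_h / params.unstable_survival_h)
    removed = []
    for a, b, d in list(net.graph.edges(data=True)):
        if d["sprout"] or d["w"] > w_threshold:
            continue
        if d["f"] >= params.critical_shear_kpa:
            continue
        if rng.random() < p:
            net.remove_segment(a, b)
            removed.append((a, b))
    return removed


# --------------------------------------------------------------------------
# master loop
# --------------------------------------------------------------------------

@dataclass
class GrowthLog:
    steps: list = field(default_factory=list)   # dicts of per-step event counts


def growth_step(net: VesselNetwork, state: ContinuumState,
                params: GrowthParams, master_seed: int, step_index: int,
                sampling_density: float = 2e-3) -> dict:
    """One 1 h step of the coupled vessel-tissue system.

    Fixed rule order: flow solve -> sprout initiation -> migration ->
    degeneration -> dilation -> collapse -> continuum sub-steps (phases,
    level set with redistancing, oxygen and growth-factor refresh).
    """
    dt_h = params.dt_vessel_h
    rng_init = named_stream(master_seed, "initiation", str(step_index))
    rng_migr = named_stream(master_seed, "migration", str(step_index))
    rng_coll = named_stream(master_seed, "collapse", str(step_index))
    rng_samp = named_stream(master_seed, "sampling", str(step_index))

    sol = solve_nodal_pressures(net, plasma_viscosity=params.plasma_viscosity,
                                hematocrit=params.hematocrit)
    apply_flow(net, sol)
    update_tumor_flags(net, state, dt_h)

    n_spr = len(sprout_initiation(net, state, params, rng_init, dt_h))
    n_mig = sprout_migration(net, state, params, rng_migr, dt_h)
    degrade_walls(net, params, dt_h)
    n_dil = dilate_vessels(net, state, params, dt_h)
    n_col = len(maybe_collapse(net, params, rng_coll, dt_h))

    # continuum: phases + level set, sub-stepped to the advective CFL
    from .continuum import stable_dt_phases
    elapsed = 0.0
    while elapsed < dt_h - 1e-12:
        press = solid_pressure(state.phi_cells, params)
        v = cell_velocity(state.grid, press, params)
        sub = min(dt_h - elapsed, stable_dt_phases(state, v, params))
        new = advance_phases(state, v, sub, params)
        theta = advect_levelset(state.grid, state.theta, v, sub)
        state.phi_T, state.phi_N, state.phi_D = new.phi_T, new.phi_N, new.phi_D
        state.theta = theta
        elapsed += sub
    state.theta = redistance(state.grid, state.theta,
                             iterations=max(10, int(0.5 * max(state.grid.shape))))

    if net.n_segments:
        samp = sample_surfaces(net, state.grid, rng_samp,
                               density=sampling_density)
        state.c = oxygen_field(state, samp, params)
    else:
        state.c = state.grid.zeros()
    state.g = growth_factor_field(state, params)

    net.validate()
    return {"step": step_index, "sprouts": n_spr, "migrations": n_mig,
            "dilations": n_dil, "collapses": n_col,
            "segments": net.n_segments}


def run_growth(net: VesselNetwork, state: ContinuumState,
               params: GrowthParams, master_seed: int, t_end_h: float,
               sampling_density: float = 2e-3) -> GrowthLog:
    """Advance the coupled system to t_end in 1 h network steps."""
    log = GrowthLog()
    nsteps = int(round(t_end_h / params.dt_vessel_h))
    for k in range(nsteps):
        log.steps.append(growth_step(net, state, params, master_seed, k,
                                     sampling_density))
    return log
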