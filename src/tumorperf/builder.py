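"""Construction of the hierarchical arteriovenous initial network.

Arterial and venous tree roots are placed alternatingly on lattice
boundary sites; trees grow by stochastically appending structural
elements (single bonds or Y-shaped triples) to leaves until the lattice
is filled; capillaries are inserted between neighboring arterial and
venous terminals; shear-stress-driven remodeling then stochastically
removes low-shear and extends high-shear terminal branches until the
capillary count plateaus.  Radii follow Murray's law up the trees.  An
outer up-scaling loop (subdivide, regrow from the previous terminals)
produces the hierarchical morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hemodynamics import apply_flow, solve_nodal_pressures
from .lattice import Lattice, VesselNetwork, subdivide_network
from .params import GrowthParams


@dataclass
class BuilderConfig:
    extent: tuple[int, ...] = (13, 16)     # desk-scale default (2D triangular)
    spacing: float = 40.0                  # µm, inter-capillary distance lattice
    n_roots: int = 4
    upscaling_steps: int = 0
    capillary_radius: float = 4.0
    arterial_terminal_radius: float = 5.0
    venous_terminal_radius: float = 7.0
    murray_alpha: float = 3.0
    y_element_prob: float = 0.5            # Y-aggregate vs single bond
    remodel_p0: float = 0.5                # base attach/remove probability scale
    plateau_window: int = 20
    plateau_tol: float = 0.02
    max_sweeps: int = 200
    seed: int = 0

    @classmethod
    def from_params(cls, p: GrowthParams, **over) -> "BuilderConfig":
        kw = dict(
            spacing=p.builder_spacing,
            upscaling_steps=p.upscaling_steps,
            capillary_radius=p.capillary_radius,
            arterial_terminal_radius=p.arterial_terminal_radius,
            venous_terminal_radius=p.venous_terminal_radius,
            murray_alpha=p.murray_alpha,
            plateau_window=p.plateau_window,
            plateau_tol=p.plateau_tol,
        )
        kw.update(over)
        return cls(**kw)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def place_roots(lat: Lattice, n_roots: int,
                rng: np.random.Generator) -> VesselNetwork:
    """Place arterial/venous roots alternatingly along the boundary."""
    boundary = lat.boundary_sites()
    if not boundary:
        raise ValueError("lattice has no boundary sites")
    n_roots = min(n_roots, len(boundary))
    picks = np.sort(rng.choice(len(boundary), size=n_roots, replace=False))
    net = VesselNetwork(lat)
    for i, k in enumerate(picks):
        kind = "arterial" if i % 2 == 0 else "venous"
        net.add_node(boundary[int(k)], bc=kind)
        net.graph.nodes[boundary[int(k)]]["side"] = kind
    return net


def _free_neighbors(net: VesselNetwork, s) -> list:
    return [t for t in net.lattice.neighbors(s)
            if not net.bond_occupied(s, t) and t not in net.graph]


def grow_trees(net: VesselNetwork, rng: np.random.Generator,
               y_prob: float = 0.5, leaves: list | None = None,
               max_elements: int | None = None) -> VesselNetwork:
    """Stage one: fill the lattice with cycle-free trees.

    Elements (single vessels or Y-aggregates of three) are appended at
    randomly chosen leaves onto free bonds toward unoccupied sites; the
    stage ends when no leaf admits a legal attachment.
    """
    if leaves is None:
        leaves = list(net.roots())
    active = list(leaves)
    n_added = 0
    while active:
        if max_elements is not None and n_added >= max_elements:
            break
        i = int(rng.integers(len(active)))
        leaf = active[i]
        free = _free_neighbors(net, leaf)
        if not free:
            active.pop(i)
            continue
        side = net.graph.nodes[leaf].get("side")
        use_y = rng.random() < y_prob and len(free) >= 2
        if use_y:
            picks = rng.choice(len(free), size=2, replace=False)
            stem = free[int(picks[0])]
            net.add_segment(leaf, stem, tree=True)
            net.graph.nodes[stem]["side"] = side
            branch_free = _free_neighbors(net, stem)
            rng.shuffle(branch_free)
            new_leaves = []
            for t in branch_free[:2]:
                net.add_segment(stem, t, tree=True)
                net.graph.nodes[t]["side"] = side
                new_leaves.append(t)
            if not new_leaves:
                new_leaves = [stem]
            active.extend(new_leaves)
            n_added += 1 + len(new_leaves)
        else:
            t = free[int(rng.integers(len(free)))]
            net.add_segment(leaf, t, tree=True)
            net.graph.nodes[t]["side"] = side
            active.append(t)
            n_added += 1
    return net


def terminals(net: VesselNetwork, side: str | None = None) -> list:
    """Degree-1 non-root tree nodes (candidate capillary anchors)."""
    out = []
    for s in net.graph.nodes:
        if net.graph.degree(s) != 1 or net.graph.nodes[s].get("bc"):
            continue
        if side is None or net.graph.nodes[s].get("side") == side:
            out.append(s)
    return out


def insert_capillaries(net: VesselNetwork, r_cap: float = 4.0,
                       max_bonds: int = 2) -> int:
    """Bridge neighboring arterial and venous terminals with capillaries.

    Capillaries are straight segments along free lattice bonds, at most
    ``max_bonds`` long (vessels may span several bonds but must be
    straight).
    """
    from .lattice import bond_path
    art = set(terminals(net, "arterial"))
    ven = set(terminals(net, "venous"))
    n = 0
    for a in sorted(art):
        for k in range(1, max_bonds + 1):
            placed = False
            for off in net.lattice.offsets:
                t = tuple(c + k * o for c, o in zip(a, off))
                if not net.lattice.valid_site(t) or t not in ven:
                    continue
                if net.graph.has_edge(a, t):
                    continue
                bonds = bond_path(a, t)
                if any(net.bond_occupied(u, v) for u, v in bonds):
                    continue
                inner = {s for u, v in bonds for s in (u, v)} - {a, t}
                if any(s in net.graph for s in inner):
                    continue
                net.add_segment(a, t, r=r_cap, capillary=True)
                n += 1
                placed = True
                break
            if placed:
                break
    return n


def remove_capillaries(net: VesselNetwork) -> None:
    for a, b, d in list(net.graph.edges(data=True)):
        if d.get("capillary"):
            net.remove_segment(a, b)


def assign_murray_radii(net: VesselNetwork, alpha: float = 3.0,
                        r_art: float = 5.0, r_ven: float = 7.0) -> None:
    """Set terminal radii per side and propagate Murray's law to the roots.

    At every branching r_parent^alpha = sum of r_child^alpha; a cycle
    within a tree is an error.
    """
    import networkx as nx
    tree_edges = [(a, b) for a, b, d in net.graph.edges(data=True)
                  if not d.get("capillary")]
    sub = net.graph.edge_subgraph(tree_edges).copy() if tree_edges else None
    if sub is None:
        return
    for root in net.roots():
        if root not in sub:
            continue
        comp = nx.node_connected_component(sub, root)
        view = sub.subgraph(comp)
        if view.number_of_edges() >= view.number_of_nodes():
            raise ValueError(f"cycle within tree rooted at {root}")
        side = net.graph.nodes[root].get("side", "arterial")
        r_term = r_art if side == "arterial" else r_ven
        order = list(nx.bfs_tree(view, root).edges())   # root -> leaves
        radii: dict = {}
        for parent, child in reversed(order):
            children = [c for p, c in order if p == child]
            if not children:
                radii[(parent, child)] = r_term
            else:
                radii[(parent, child)] = (
                    sum(radii[(child, c)] ** alpha for c in children)
                ) ** (1.0 / alpha)
        for (p, c), r in radii.items():
            net.graph.edges[p, c]["r"] = r


def terminal_probabilities(shears: np.ndarray, p0: float = 0.5,
                           eps: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Monotone rank map shear -> (attach, remove) probabilities.

    High shear favors growth, low shear favors removal; ranks keep the
    map free of unprinted constants and bounded away from 0 and 1.
    Equal shears give equal attach and remove probabilities.
    """
    n = len(shears)
    if n == 0:
        return np.zeros(0), np.zeros(0)
    order = np.argsort(np.argsort(shears, kind="stable"), kind="stable")
    # average ranks for ties so identical shears get identical probabilities
    uniq, inv = np.unique(shears, return_inverse=True)
    mean_rank = np.zeros(len(uniq))
    np.add.at(mean_rank, inv, order.astype(float))
    counts = np.bincount(inv)
    mean_rank /= counts
    u = (mean_rank[inv] + 0.5) / n
    u = np.clip(u, eps, 1.0 - eps)
    return p0 * u, p0 * (1.0 - u)


def shear_remodel(net: VesselNetwork, cfg: BuilderConfig,
                  rng: np.random.Generator,
                  params: GrowthParams | None = None) -> list[int]:
    """Stage two: shear-driven growth/shrinkage until a capillary plateau.

    Each sweep: capillarize, assign radii, solve flow, then remove or
    extend terminal branches with rank-based probabilities; stops when
    the moving-average capillary count changes by less than the tolerance
    over the plateau window.  Returns the capillary-count history.
    """
    p = params or GrowthParams()
    history: list[int] = []
    for sweep in range(cfg.max_sweeps):
        remove_capillaries(net)
        assign_murray_radii(net, cfg.murray_alpha,
                            cfg.arterial_terminal_radius,
                            cfg.venous_terminal_radius)
        n_cap = insert_capillaries(net, cfg.capillary_radius)
        history.append(n_cap)
        try:
            sol = solve_nodal_pressures(net, plasma_viscosity=p.plasma_viscosity,
                                        hematocrit=p.hematocrit)
            apply_flow(net, sol)
        except Exception:
            pass

        terms = []
        for s in terminals(net):
            (t,) = list(net.graph.neighbors(s))
            e = net.graph.edges[s, t]
            if not e.get("capillary"):
                terms.append((s, t, e.get("f", 0.0)))
        if terms:
            shears = np.array([f for _, _, f in terms])
            p_att, p_rem = terminal_probabilities(shears, cfg.remodel_p0)
            draws = rng.random(len(terms))
            for (s, t, _f), pa, pr, u in zip(terms, p_att, p_rem, draws):
                if u < pr:
                    if net.graph.has_edge(s, t):
                        net.remove_segment(s, t)
                elif u < pr + pa:
                    free = _free_neighbors(net, s)
                    if free:
                        nxt = free[int(rng.integers(len(free)))]
                        net.add_segment(s, nxt, tree=True)
                        net.graph.nodes[nxt]["side"] = net.graph.nodes[s].get("side")

        if len(history) >= cfg.plateau_window and history[-1] > 0:
            win = history[-cfg.plateau_window:]
            half = cfg.plateau_window // 2
            m1 = np.mean(win[:half])
            m2 = np.mean(win[half:])
            if m1 > 0 and abs(m2 - m1) / m1 < cfg.plateau_tol:
                break
    return history


def construct_initial_network(cfg: BuilderConfig,
                              params: GrowthParams | None = None
                              ) -> tuple[VesselNetwork, list[int]]:
    """Full staged construction with hierarchical up-scaling.

    Returns the final capillarized, Murray-consistent, flow-solved
    network and the capillary-count log of the last remodeling stage.
    Deterministic for a fixed config seed.
    """
    from .rng import named_stream
    lat = Lattice(extent=cfg.extent, spacing=cfg.spacing,
                  kind="fcc" if len(cfg.extent) == 3 else "tri")
    rng = named_stream(cfg.seed, "network-build")
    net = place_roots(lat, cfg.n_roots, rng)
    grow_trees(net, rng, cfg.y_element_prob)
    history = shear_remodel(net, cfg, rng, params)

    for step in range(cfg.upscaling_steps):
        remove_capillaries(net)
        net, lat = subdivide_network(net, lat)
        new_leaves = terminals(net)
        grow_trees(net, rng, cfg.y_element_prob, leaves=new_leaves)
        history = shear_remodel(net, cfg, rng, params)

    remove_capillaries(net)
    n_cap = insert_capillaries(net, cfg.capillary_radius)
    if n_cap:   # pruning without any capillaries would consume whole trees
        _prune_unperfused_leaves(net)
    assign_murray_radii(net, cfg.murray_alpha,
                        cfg.arterial_terminal_radius,
                        cfg.venous_terminal_radius)
    p = params or GrowthParams()
    sol = solve_nodal_pressures(net, plasma_viscosity=p.plasma_viscosity,
                                hematocrit=p.hematocrit)
    apply_flow(net, sol)
    net.validate()
    return net, history


def _prune_unperfused_leaves(net: VesselNetwork, max_rounds: int = 200) -> None:
    """Iteratively drop dangling terminal branches that cannot conduct."""
    for _ in range(max_rounds):
        dead = [s for s in net.graph.nodes
                if net.graph.degree(s) == 1 and not net.graph.nodes[s].get("bc")
                and not any(net.graph.edges[s, t].get("capillary")
                            for t in net.graph.neighbors(s))]
        if not dead:
            return
        for s in dead:
            (t,) = list(net.graph.neighbors(s))
            net.remove_segment(s, t)
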