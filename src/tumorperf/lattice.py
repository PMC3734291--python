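"""Vessel lattices and the vessel-network graph.

Vessels live on the bonds of a face-centered-cubic lattice (12 nearest
neighbors, 60-degree angles between distinct bond directions), or, in the
2D desk-scale mode, on a triangular lattice (its 2D analogue with 6
neighbors and the same 60-degree geometry).  Sites are addressed by exact
integer index tuples; geometry (positions, lengths, directions) is always
derived from indices and the lattice constant, never stored.

A vessel segment connects two lattice sites and must be straight: its
index offset is an integer multiple of a single nearest-neighbor offset.
The bonds it covers are tracked so that two segments can never overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

# 12 FCC nearest-neighbor offsets: all permutations of (+-1, +-1, 0)
FCC_OFFSETS: tuple[tuple[int, ...], ...] = tuple(
    sorted({(a, b, 0) for a in (-1, 1) for b in (-1, 1)}
           | {(a, 0, b) for a in (-1, 1) for b in (-1, 1)}
           | {(0, a, b) for a in (-1, 1) for b in (-1, 1)})
)

# 6 triangular-lattice neighbor offsets (axial coordinates)
TRI_OFFSETS: tuple[tuple[int, ...], ...] = (
    (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))

Site = tuple[int, ...]


@dataclass(frozen=True)
class Lattice:
    """FCC (3D) or triangular (2D) lattice with derived geometry."""

    extent: tuple[int, ...]          # sites per axis (index bounds)
    spacing: float                   # µm, nearest-neighbor (bond) distance
    origin: tuple[float, ...] = None  # type: ignore[assignment]
    kind: str = "fcc"                # "fcc" | "tri"

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("lattice spacing must be positive")
        if any(e < 2 for e in self.extent):
            raise ValueError("lattice extent must be >= 2 per axis")
        if self.kind not in ("fcc", "tri"):
            raise ValueError(f"unknown lattice kind {self.kind!r}")
        if self.kind == "fcc" and len(self.extent) != 3:
            raise ValueError("fcc lattice requires a 3-component extent")
        if self.kind == "tri" and len(self.extent) != 2:
            raise ValueError("triangular lattice requires a 2-component extent")
        if self.origin is None:
            object.__setattr__(self, "origin", (0.0,) * len(self.extent))

    # -- geometry -----------------------------------------------------------
    @property
    def ndim(self) -> int:
        return len(self.extent)

    @property
    def offsets(self) -> tuple[tuple[int, ...], ...]:
        return FCC_OFFSETS if self.kind == "fcc" else TRI_OFFSETS

    def valid_site(self, s: Site) -> bool:
        if len(s) != self.ndim:
            return False
        if any(not (0 <= c < e) for c, e in zip(s, self.extent)):
            return False
        if self.kind == "fcc" and sum(s) % 2 != 0:
            return False
        return True

    def position(self, s: Site) -> np.ndarray:
        """Cartesian position of a site in µm."""
        s = np.asarray(s, dtype=float)
        if self.kind == "fcc":
            return np.asarray(self.origin) + s * (self.spacing / math.sqrt(2.0))
        i, j = s
        return np.asarray(self.origin) + self.spacing * np.array(
            [i + 0.5 * j, (math.sqrt(3.0) / 2.0) * j])

    def neighbors(self, s: Site) -> Iterator[Site]:
        for off in self.offsets:
            t = tuple(a + b for a, b in zip(s, off))
            if self.valid_site(t):
                yield t

    def sites(self) -> Iterator[Site]:
        if self.kind == "fcc":
            for i in range(self.extent[0]):
                for j in range(self.extent[1]):
                    for k in range(self.extent[2]):
                        if (i + j + k) % 2 == 0:
                            yield (i, j, k)
        else:
            for i in range(self.extent[0]):
                for j in range(self.extent[1]):
                    yield (i, j)

    def is_boundary(self, s: Site) -> bool:
        return any(c == 0 or c == e - 1 for c, e in zip(s, self.extent))

    def boundary_sites(self) -> list[Site]:
        """Boundary sites in a deterministic traversal order."""
        return [s for s in self.sites() if self.is_boundary(s)]

    def refined(self) -> "Lattice":
        """Halve the spacing, double the site count (used by subdivision)."""
        return Lattice(
            extent=tuple(2 * e - 1 for e in self.extent),
            spacing=self.spacing / 2.0, origin=self.origin, kind=self.kind)

    def respaced(self, spacing: float) -> "Lattice":
        return Lattice(extent=self.extent, spacing=spacing,
                       origin=self.origin, kind=self.kind)


def build_lattice(extent: Iterable[int], spacing: float,
                  kind: str | None = None) -> Lattice:
    """Construct an FCC (3 extents) or triangular (2 extents) lattice."""
    extent = tuple(int(e) for e in extent)
    if kind is None:
        kind = "fcc" if len(extent) == 3 else "tri"
    return Lattice(extent=extent, spacing=spacing, kind=kind)


def bond_direction(a: Site, b: Site) -> tuple[tuple[int, ...], int]:
    """Decompose b - a into (unit neighbor offset, bond count).

    Raises ValueError if the segment is not straight along a lattice bond
    direction or has zero length.
    """
    d = tuple(y - x for x, y in zip(a, b))
    if all(c == 0 for c in d):
        raise ValueError("zero-length segment")
    g = math.gcd(*(abs(c) for c in d))
    unit = tuple(c // g for c in d)
    return unit, g


def bond_path(a: Site, b: Site) -> list[tuple[Site, Site]]:
    """The lattice bonds covered by a straight segment from a to b."""
    unit, n = bond_direction(a, b)
    sites = [tuple(x + i * u for x, u in zip(a, unit)) for i in range(n + 1)]
    return [(sites[i], sites[i + 1]) for i in range(n)]


def _bond_key(u: Site, v: Site) -> tuple[Site, Site]:
    return (u, v) if u <= v else (v, u)


class VesselNetwork:
    """Graph of vessel segments embedded on a lattice.

    Nodes are lattice sites carrying blood pressure ``press`` (kPa) and a
    boundary-condition tag ``bc`` in {"arterial", "venous", None}.  Edges
    carry radius ``r`` (µm), wall maturity ``w`` (µm), hematocrit ``htc``,
    flow ``q`` (µm³/s), shear ``f`` (kPa) and the flags ``sprout``,
    ``tumor``, ``perfused`` plus the clocks ``sprout_age_h`` and
    ``time_in_tumor_h``.
    """

    EDGE_DEFAULTS = dict(r=4.0, w=1.0, htc=0.45, q=0.0, f=0.0,
                         sprout=False, tumor=False, perfused=False,
                         sprout_age_h=0.0, time_in_tumor_h=0.0)

    def __init__(self, lattice: Lattice):
        self.lattice = lattice
        self.graph = nx.Graph()
        self._occupied: dict[tuple[Site, Site], tuple[Site, Site]] = {}

    # -- construction -------------------------------------------------------
    def add_node(self, site: Site, bc: str | None = None, press: float = float("nan")):
        if not self.lattice.valid_site(site):
            raise ValueError(f"site {site} not on lattice")
        if bc not in (None, "arterial", "venous"):
            raise ValueError(f"unknown boundary tag {bc!r}")
        self.graph.add_node(site, bc=bc, press=press)

    def add_segment(self, a: Site, b: Site, **attrs) -> tuple[Site, Site]:
        for s in (a, b):
            if not self.lattice.valid_site(s):
                raise ValueError(f"site {s} not on lattice")
        unit, _n = bond_direction(a, b)
        if unit not in self.lattice.offsets:
            raise ValueError(
                f"segment {a}-{b} does not follow a lattice bond direction")
        bonds = bond_path(a, b)
        for bond in bonds:
            key = _bond_key(*bond)
            if key in self._occupied:
                raise ValueError(f"bond {key} already occupied")
        if self.graph.has_edge(a, b):
            raise ValueError(f"duplicate segment {a}-{b}")
        for s in (a, b):
            if s not in self.graph:
                self.add_node(s)
        data = dict(self.EDGE_DEFAULTS)
        data.update(attrs)
        if data["r"] <= 0:
            raise ValueError("segment radius must be positive")
        if data["w"] < 0:
            raise ValueError("wall maturity must be non-negative")
        self.graph.add_edge(a, b, **data)
        for bond in bonds:
            self._occupied[_bond_key(*bond)] = (a, b)
        return (a, b)

    def remove_segment(self, a: Site, b: Site, prune: bool = True):
        if not self.graph.has_edge(a, b):
            raise KeyError(f"no segment {a}-{b}")
        self.graph.remove_edge(a, b)
        for bond in bond_path(a, b):
            self._occupied.pop(_bond_key(*bond), None)
        if prune:
            for s in (a, b):
                if s in self.graph and self.graph.degree(s) == 0:
                    self.graph.remove_node(s)

    def bond_occupied(self, u: Site, v: Site) -> bool:
        return _bond_key(u, v) in self._occupied

    # -- queries ------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_segments(self) -> int:
        return self.graph.number_of_edges()

    def segments(self):
        return self.graph.edges(data=True)

    def segment_geometry(self, a: Site, b: Site) -> tuple[float, np.ndarray]:
        """(length µm, unit direction) of a straight segment."""
        _, n = bond_direction(a, b)
        pa, pb = self.lattice.position(a), self.lattice.position(b)
        d = pb - pa
        length = n * self.lattice.spacing
        return length, d / np.linalg.norm(d)

    def roots(self, kind: str | None = None) -> list[Site]:
        out = []
        for s, d in self.graph.nodes(data=True):
            if d.get("bc") is not None and (kind is None or d["bc"] == kind):
                out.append(s)
        return out

    def validate(self) -> None:
        """Referential-integrity and embedding audit; raises on violation."""
        occ: dict[tuple[Site, Site], tuple[Site, Site]] = {}
        for a, b, d in self.graph.edges(data=True):
            if not (self.lattice.valid_site(a) and self.lattice.valid_site(b)):
                raise AssertionError(f"segment endpoint off lattice: {a}-{b}")
            if d["r"] <= 0 or d["w"] < 0:
                raise AssertionError(f"invalid segment attributes on {a}-{b}")
            for bond in bond_path(a, b):
                key = _bond_key(*bond)
                if key in occ:
                    raise AssertionError(f"bond {key} doubly occupied")
                occ[key] = (a, b)
        if set(occ) != set(self._occupied):
            raise AssertionError("bond occupancy table out of sync")
        for s in self.graph.nodes:
            if self.graph.degree(s) == 0 and self.graph.nodes[s].get("bc") is None:
                raise AssertionError(f"orphan non-root node {s}")

    def copy(self) -> "VesselNetwork":
        out = VesselNetwork(self.lattice)
        out.graph = self.graph.copy()
        out._occupied = dict(self._occupied)
        return out

    # -- topology helpers ---------------------------------------------------
    def contract_degree2(self) -> "VesselNetwork":
        """Merge chains through plain degree-2 nodes into straight segments.

        Inverts subdivision on topology: inserted midpoints disappear when
        their two incident segments are collinear and attribute-identical.
        """
        out = self.copy()
        changed = True
        while changed:
            changed = False
            for s in list(out.graph.nodes):
                if out.graph.degree(s) != 2 or out.graph.nodes[s].get("bc"):
                    continue
                (n1, n2) = list(out.graph.neighbors(s))
                d1 = out.graph.edges[s, n1]
                d2 = out.graph.edges[s, n2]
                try:
                    u1, _ = bond_direction(n1, s)
                    u2, _ = bond_direction(s, n2)
                except ValueError:
                    continue
                if u1 != u2:
                    continue
                if any(d1[k] != d2[k] for k in ("r", "w", "sprout", "tumor")):
                    continue
                attrs = dict(d1)
                out.remove_segment(s, n1, prune=False)
                out.remove_segment(s, n2, prune=False)
                out.graph.remove_node(s)
                out.add_segment(n1, n2, **attrs)
                changed = True
        return out


def subdivide_network(net: VesselNetwork,
                      lat: Lattice) -> tuple[VesselNetwork, Lattice]:
    """One hierarchical up-scaling step.

    The lattice is refined (spacing halved, site count doubled), every
    segment then occupies two bonds with an inserted midpoint node, and the
    spacing is finally reset to its former value so that the spatial extent
    and all segment lengths double.
    """
    fine = lat.refined().respaced(lat.spacing)
    out = VesselNetwork(fine)
    for s, d in net.graph.nodes(data=True):
        s2 = tuple(2 * c for c in s)
        out.add_node(s2, bc=d.get("bc"), press=d.get("press", float("nan")))
        out.graph.nodes[s2].update(
            {k: v for k, v in d.items() if k not in ("bc", "press")})
    for a, b, d in net.graph.edges(data=True):
        a2 = tuple(2 * c for c in a)
        b2 = tuple(2 * c for c in b)
        mid = tuple(x + y for x, y in zip(a, b))
        attrs = {k: v for k, v in d.items()}
        out.add_segment(a2, mid, **attrs)
        out.add_segment(mid, b2, **attrs)
        # inserted midpoints inherit the auxiliary tags of an endpoint
        for k, v in net.graph.nodes[a].items():
            if k not in ("bc", "press"):
                out.graph.nodes[mid].setdefault(k, v)
    return out, fine


def total_length(net: VesselNetwork) -> float:
    return sum(net.segment_geometry(a, b)[0] for a, b, _ in net.segments())
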