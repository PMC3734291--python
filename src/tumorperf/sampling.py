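"""Stochastic uniform sampling of vessel surfaces onto the continuum grid.

Transvascular exchange (fluid, oxygen, drug) is represented by point
samples drawn uniformly from the lateral surfaces of the cylindrical
vessel segments.  Each sample carries an equal share of its segment's
surface area and the locally interpolated blood pressure, and is
deposited into grid cells through a compact smoothing kernel that is an
exact partition of unity (cloud-in-cell by default, a quartic kernel of
radius 2h as an alternative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import Grid
from .lattice import VesselNetwork


@dataclass
class SurfaceSampling:
    """Per-sample surface records plus the deposition machinery."""

    grid: Grid
    positions: np.ndarray       # (n, ndim) µm
    areas: np.ndarray           # (n,) µm² per sample
    blood_pressure: np.ndarray  # (n,) kPa, linearly interpolated along segment
    segment_index: np.ndarray   # (n,) index into `segments`
    segments: list              # list of (a, b) edge keys
    wall_w: np.ndarray          # (n,) wall maturity of owning segment (µm)
    radius: np.ndarray          # (n,) radius of owning segment (µm)
    perfused: np.ndarray        # (n,) bool
    tumor: np.ndarray           # (n,) bool
    kernel: str = "cic"

    @property
    def n_samples(self) -> int:
        return len(self.areas)

    def deposit(self, values: np.ndarray | float) -> np.ndarray:
        """Deposit per-sample scalar*area as a cell density field (per µm³).

        Returns sum_s values_s * a_s * K(x - x_s) / V_cell; the kernel K
        sums to one over cells, so the field integrates (sum * V_cell) to
        sum(values * areas) exactly.
        """
        v = np.broadcast_to(np.asarray(values, float), (self.n_samples,))
        weights = v * self.areas
        field = self.grid.zeros()
        if self.n_samples == 0:
            return field
        _deposit_kernel(self.grid, self.positions, weights, field, self.kernel)
        return field / self.grid.cell_volume

    def interpolate(self, field: np.ndarray) -> np.ndarray:
        """Evaluate a cell field at the samples with the deposition kernel.

        Using the same (adjoint) kernel for gather and scatter makes
        global exchange budgets close exactly.
        """
        if self.n_samples == 0:
            return np.zeros(0)
        if self.kernel != "cic":
            raise NotImplementedError("interpolation implemented for cic kernel")
        rel = (self.positions - np.asarray(self.grid.origin)) / self.grid.h - 0.5
        base = np.floor(rel).astype(int)
        frac = rel - base
        out = np.zeros(self.n_samples)
        for corner in np.ndindex(*(2,) * self.grid.ndim):
            w = np.ones(self.n_samples)
            idx = []
            for a in range(self.grid.ndim):
                ca = base[:, a] + corner[a]
                wa = frac[:, a] if corner[a] else 1.0 - frac[:, a]
                w = w * wa
                idx.append(np.clip(ca, 0, self.grid.shape[a] - 1))
            out += w * field[tuple(idx)]
        return out

    def surface_density(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Vessel surface area per volume (1/µm), optionally masked."""
        vals = np.ones(self.n_samples)
        if mask is not None:
            vals = vals * mask
        return self.deposit(vals)


def _deposit_kernel(grid: Grid, pos: np.ndarray, weights: np.ndarray,
                    field: np.ndarray, kernel: str) -> None:
    rel = (pos - np.asarray(grid.origin)) / grid.h - 0.5  # cell-center coords
    if kernel == "cic":
        base = np.floor(rel).astype(int)
        frac = rel - base
        for corner in np.ndindex(*(2,) * grid.ndim):
            w = weights.copy()
            idx = []
            for a in range(grid.ndim):
                ca = base[:, a] + corner[a]
                wa = frac[:, a] if corner[a] else 1.0 - frac[:, a]
                w = w * wa
                idx.append(np.clip(ca, 0, grid.shape[a] - 1))
            np.add.at(field, tuple(idx), w)
    elif kernel == "quartic":
        # radius-2h tensor-product kernel (1 - (x/2)^2)^2, renormalized per
        # sample so deposition remains an exact partition of unity
        base = np.floor(rel).astype(int)
        offs = range(-1, 3)
        wsum = np.zeros(len(weights))
        contribs = []
        for corner in np.ndindex(*(4,) * grid.ndim):
            w = np.ones(len(weights))
            idx = []
            for a in range(grid.ndim):
                ca = base[:, a] + list(offs)[corner[a]]
                x = np.abs(rel[:, a] - ca) / 2.0
                w = w * np.clip(1.0 - x ** 2, 0.0, None) ** 2
                idx.append(np.clip(ca, 0, grid.shape[a] - 1))
            contribs.append((idx, w))
            wsum += w
        for idx, w in contribs:
            np.add.at(field, tuple(idx), weights * w / wsum)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")


def sample_surfaces(net: VesselNetwork, grid: Grid, rng: np.random.Generator,
                    density: float = 2e-3, kernel: str = "cic",
                    min_samples_per_segment: int = 4) -> SurfaceSampling:
    """Sample vessel lateral surfaces uniformly at ``density`` per µm².

    Each segment of radius r and length l contributes ~density*2*pi*r*l
    samples (at least ``min_samples_per_segment``); sample areas are the
    segment surface divided by its sample count, so per-segment area is
    conserved exactly.
    """
    if density <= 0:
        raise ValueError("sampling density must be positive")
    segs, pos, areas, pb, sidx, ww, rad, perf, tum = ([] for _ in range(9))
    for k, (a, b, d) in enumerate(net.segments()):
        length, direction = net.segment_geometry(a, b)
        r = d["r"]
        surface = 2.0 * math.pi * r * length
        n = max(min_samples_per_segment, int(round(density * surface)))
        t = rng.uniform(0.0, 1.0, n)                 # axial fraction
        phi = rng.uniform(0.0, 2.0 * math.pi, n)     # azimuth
        pa = net.lattice.position(a)
        axis = direction
        # orthonormal frame around the axis
        if net.lattice.ndim == 3:
            ref = np.array([1.0, 0.0, 0.0])
            if abs(axis @ ref) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            e1 = np.cross(axis, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(axis, e1)
            radial = (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
        else:
            e1 = np.array([-axis[1], axis[0]])
            radial = np.cos(phi)[:, None] * e1[None, :]
        p = pa[None, :] + t[:, None] * length * axis[None, :] + r * radial
        p_a = net.graph.nodes[a].get("press", np.nan)
        p_b = net.graph.nodes[b].get("press", np.nan)
        segs.append((a, b))
        pos.append(p)
        areas.append(np.full(n, surface / n))
        pb.append(p_a + t * (p_b - p_a))
        sidx.append(np.full(n, k, dtype=int))
        ww.append(np.full(n, d["w"]))
        rad.append(np.full(n, r))
        perf.append(np.full(n, bool(d.get("perfused", False))))
        tum.append(np.full(n, bool(d.get("tumor", False))))

    if not segs:
        z = np.zeros((0,))
        return SurfaceSampling(grid, np.zeros((0, grid.ndim)), z, z,
                               np.zeros(0, int), [], z, z,
                               np.zeros(0, bool), np.zeros(0, bool), kernel)
    return SurfaceSampling(
        grid,
        np.concatenate(pos), np.concatenate(areas), np.concatenate(pb),
        np.concatenate(sidx), segs, np.concatenate(ww), np.concatenate(rad),
        np.concatenate(perf), np.concatenate(tum), kernel)
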