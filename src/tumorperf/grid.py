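"""Uniform staggered grid and shared numerical kernels.

Scalars (volume fractions, pressures, concentrations, the level set) are
cell-centered; velocities and fluxes live on cell faces.  The same kernels
serve the tissue dynamics, the interstitial-flow solve and the drug
transport: a finite-volume elliptic solver with harmonically averaged
face conductivities, a second-order central-upwind (MUSCL/minmod)
advection flux, and an explicit diffusion operator.

Works in 2 or 3 dimensions; all operators are dimension-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


@dataclass(frozen=True)
class Grid:
    shape: tuple[int, ...]
    h: float                      # µm
    origin: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("grid spacing must be positive")
        if self.origin is None:
            object.__setattr__(self, "origin", (0.0,) * len(self.shape))

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def cell_volume(self) -> float:
        return self.h ** self.ndim

    def axes(self) -> list[np.ndarray]:
        """Cell-center coordinates along each axis (µm)."""
        return [self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.h
                for a in range(self.ndim)]

    def meshgrid(self) -> list[np.ndarray]:
        return list(np.meshgrid(*self.axes(), indexing="ij"))

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape)

    def face_shape(self, axis: int) -> tuple[int, ...]:
        s = list(self.shape)
        s[axis] += 1
        return tuple(s)

    def zero_faces(self) -> list[np.ndarray]:
        return [np.zeros(self.face_shape(a)) for a in range(self.ndim)]

    def cell_index(self, pos: np.ndarray) -> tuple[int, ...]:
        """Cell containing a position (clipped to the domain)."""
        rel = (np.asarray(pos, float) - np.asarray(self.origin)) / self.h
        ij = np.floor(rel).astype(int)
        return tuple(int(np.clip(ij[a], 0, self.shape[a] - 1))
                     for a in range(self.ndim))


def _faces_slices(axis: int, ndim: int):
    lo = [slice(None)] * ndim
    hi = [slice(None)] * ndim
    lo[axis] = slice(None, -1)
    hi[axis] = slice(1, None)
    return tuple(lo), tuple(hi)


def gradient_faces(grid: Grid, u: np.ndarray) -> list[np.ndarray]:
    """Face-centered gradient; boundary faces carry zero (no-flux)."""
    out = grid.zero_faces()
    for a in range(grid.ndim):
        lo, hi = _faces_slices(a, grid.ndim)
        interior = [slice(None)] * grid.ndim
        interior[a] = slice(1, -1)
        out[a][tuple(interior)] = (u[hi] - u[lo]) / grid.h
    return out


def divergence(grid: Grid, faces: list[np.ndarray]) -> np.ndarray:
    """Cell-centered divergence of face fluxes."""
    out = grid.zeros()
    for a in range(grid.ndim):
        lo = [slice(None)] * grid.ndim
        hi = [slice(None)] * grid.ndim
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        out += (faces[a][tuple(hi)] - faces[a][tuple(lo)]) / grid.h
    return out


def face_harmonic(grid: Grid, k: np.ndarray) -> list[np.ndarray]:
    """Harmonic mean of a cell conductivity on interior faces (0 on boundary)."""
    out = grid.zero_faces()
    for a in range(grid.ndim):
        lo, hi = _faces_slices(a, grid.ndim)
        interior = [slice(None)] * grid.ndim
        interior[a] = slice(1, -1)
        kl, kr = k[lo], k[hi]
        with np.errstate(divide="ignore", invalid="ignore"):
            hm = np.where(kl + kr > 0, 2.0 * kl * kr / (kl + kr), 0.0)
        out[a][tuple(interior)] = hm
    return out


class SingularSystemError(RuntimeError):
    """Pure-Neumann elliptic problem without any absorption or anchor."""


def elliptic_solve(grid: Grid, conductivity: np.ndarray,
                   absorption: np.ndarray | float = 0.0,
                   source: np.ndarray | float = 0.0,
                   dirichlet_mask: np.ndarray | None = None,
                   dirichlet_values: np.ndarray | float = 0.0,
                   tol: float = 1e-12,
                   direct_threshold: int = 70000) -> np.ndarray:
    """Solve div(K grad u) - a u + b = 0 with zero-flux outer boundaries.

    ``conductivity`` (K) is cell-centered and harmonically averaged onto
    faces; ``absorption`` (a >= 0) and ``source`` (b) are cell fields or
    scalars; cells in ``dirichlet_mask`` are pinned to
    ``dirichlet_values``.  Without any absorption or Dirichlet anchor the
    problem is singular and raises :class:`SingularSystemError`.
    """
    shape = grid.shape
    n = grid.n_cells
    a = np.broadcast_to(np.asarray(absorption, float), shape)
    b = np.broadcast_to(np.asarray(source, float), shape)
    if np.any(a < 0):
        raise ValueError("absorption must be non-negative")
    has_anchor = np.any(a > 0) or (
        dirichlet_mask is not None and np.any(dirichlet_mask))
    if not has_anchor:
        raise SingularSystemError(
            "no sink anchors the pressure level: need absorption (lymphatics/"
            "consumption) or a Dirichlet boundary cell")

    idx = np.arange(n).reshape(shape)
    h2 = grid.h ** 2
    kf = face_harmonic(grid, np.broadcast_to(np.asarray(conductivity, float), shape))

    diag = a.ravel().copy()
    rows, cols, vals = [], [], []
    for ax in range(grid.ndim):
        lo, hi = _faces_slices(ax, grid.ndim)
        interior = [slice(None)] * grid.ndim
        interior[ax] = slice(1, -1)
        t = kf[ax][tuple(interior)] / h2       # transmissibility between lo/hi cells
        i, j = idx[lo].ravel(), idx[hi].ravel()
        tv = t.ravel()
        rows.extend((i, j))
        cols.extend((j, i))
        vals.extend((-tv, -tv))
        np.add.at(diag, i, tv)
        np.add.at(diag, j, tv)

    rows = np.concatenate([np.concatenate(rows), np.arange(n)])
    cols = np.concatenate([np.concatenate(cols), np.arange(n)])
    vals = np.concatenate([np.concatenate(vals), diag])
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    rhs = b.ravel().copy()

    if dirichlet_mask is not None and np.any(dirichlet_mask):
        dvals = np.broadcast_to(np.asarray(dirichlet_values, float), shape).ravel()
        mask = np.asarray(dirichlet_mask, bool).ravel()
        fixed = np.where(mask)[0]
        mat = mat.tolil()
        for i in fixed:
            mat.rows[i] = [i]
            mat.data[i] = [1.0]
        mat = mat.tocsr()
        rhs[fixed] = dvals[fixed]
        u = spla.spsolve(mat.tocsc(), rhs)
        return u.reshape(shape)

    if n <= direct_threshold:
        u = spla.spsolve(mat.tocsc(), rhs)
    else:
        prec = sp.diags(1.0 / mat.diagonal())
        u, info = spla.cg(mat, rhs, rtol=tol, maxiter=5000, M=prec)
        if info != 0:
            raise RuntimeError(f"elliptic solve did not converge (info={info})")
    return u.reshape(shape)


# --------------------------------------------------------------------------
# advection / diffusion kernels
# --------------------------------------------------------------------------

def _minmod(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.where(a * b > 0, np.where(np.abs(a) < np.abs(b), a, b), 0.0)


def advective_flux(grid: Grid, u_faces: list[np.ndarray],
                   phi: np.ndarray) -> list[np.ndarray]:
    """Second-order upwind (MUSCL/minmod central-upwind) flux of phi.

    Boundary faces use the outer face velocity with edge-extended ghost
    cells (outflow boundaries).
    """
    fluxes = []
    for ax in range(grid.ndim):
        pad = [(0, 0)] * grid.ndim
        pad[ax] = (2, 2)
        pg = np.pad(phi, pad, mode="edge")

        def sl(off_lo, off_hi=None):
            s = [slice(None)] * grid.ndim
            s[ax] = slice(off_lo, off_hi)
            return tuple(s)

        dphi = pg[sl(1, None)] - pg[sl(None, -1)]            # differences
        slope = _minmod(dphi[sl(1, None)], dphi[sl(None, -1)])  # per padded cell (minus outermost)
        # left/right states at each face: faces k = 0..n between padded cells
        left = pg[sl(1, -2)] + 0.5 * slope[sl(None, -1)]
        right = pg[sl(2, -1)] - 0.5 * slope[sl(1, None)]
        uf = u_faces[ax]
        fluxes.append(np.where(uf >= 0, uf * left, uf * right))
    return fluxes


def advect(grid: Grid, phi: np.ndarray, u_faces: list[np.ndarray],
           dt: float, check_cfl: bool = True) -> np.ndarray:
    """One conservative advection step of d(phi)/dt + div(u phi) = 0.

    Second-order in space (MUSCL) with Heun (improved Euler) time stepping.
    """
    if check_cfl:
        dtmax = cfl_dt_advection(grid, u_faces)
        if dt > dtmax * (1 + 1e-12):
            raise ValueError(f"advective CFL violated: dt={dt:g} > {dtmax:g}")

    def rhs(p):
        return -divergence(grid, advective_flux(grid, u_faces, p))

    k1 = rhs(phi)
    k2 = rhs(phi + dt * k1)
    return phi + 0.5 * dt * (k1 + k2)


def diffuse_explicit(grid: Grid, phi: np.ndarray, d_coeff: np.ndarray | float,
                     dt: float) -> np.ndarray:
    """One explicit diffusion step with face-harmonic coefficients."""
    dcell = np.broadcast_to(np.asarray(d_coeff, float), grid.shape)
    dtmax = cfl_dt_diffusion(grid, float(np.max(dcell)))
    if dt > dtmax * (1 + 1e-12):
        raise ValueError(f"diffusive stability violated: dt={dt:g} > {dtmax:g}")
    kf = face_harmonic(grid, dcell)
    g = gradient_faces(grid, phi)
    return phi + dt * divergence(grid, [kf[a] * g[a] for a in range(grid.ndim)])


def cfl_dt_advection(grid: Grid, u_faces: list[np.ndarray],
                     safety: float = 1.0) -> float:
    umax = sum(float(np.max(np.abs(f))) for f in u_faces)
    if umax == 0:
        return np.inf
    return safety * grid.h / umax


def cfl_dt_diffusion(grid: Grid, dmax: float, safety: float = 1.0) -> float:
    if dmax <= 0:
        return np.inf
    return safety * grid.h ** 2 / (2.0 * grid.ndim * dmax)
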