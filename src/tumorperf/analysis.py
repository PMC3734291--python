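"""Post-processing: radial profiles, exponential penetration fits,
region summaries and fluid-source aggregates.

Grid fields are sorted into shells of the signed distance to the tumor
surface (theta); vessel-borne quantities are sampled on segment center
lines and binned the same way.  Ensemble statistics (mean and standard
deviation across runs) are computed over per-run bin means, never by
pooling cells across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .grid import Grid
from .iff import SourceField


# --------------------------------------------------------------------------
# radial (theta) profiles
# --------------------------------------------------------------------------

@dataclass
class RadialProfile:
    centers: np.ndarray          # bin centers in theta (µm)
    mean: np.ndarray             # ensemble mean of per-run bin means
    std: np.ndarray              # ensemble STD across runs (0 for one run)
    counts: np.ndarray           # total samples per bin
    missing: np.ndarray          # bins with no samples in any run


def _bin_means(values: np.ndarray, theta: np.ndarray,
               edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = np.digitize(theta.ravel(), edges) - 1
    nb = len(edges) - 1
    ok = (idx >= 0) & (idx < nb)
    sums = np.bincount(idx[ok], weights=values.ravel()[ok], minlength=nb)
    counts = np.bincount(idx[ok], minlength=nb)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def theta_profile(runs: list[tuple[np.ndarray, np.ndarray]],
                  bin_width: float = 100.0,
                  theta_range: tuple[float, float] | None = None
                  ) -> RadialProfile:
    """Profile of a field vs signed distance to the tumor edge.

    ``runs`` is a list of (field, theta) pairs, one per simulation run.
    Per-run bin means are averaged across the ensemble; empty bins are
    flagged missing, not zero.
    """
    if not runs:
        raise ValueError("no runs given")
    if theta_range is None:
        lo = min(float(np.min(t)) for _, t in runs)
        hi = max(float(np.max(t)) for _, t in runs)
    else:
        lo, hi = theta_range
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    per_run = []
    counts = np.zeros(len(edges) - 1)
    for f, t in runs:
        m, c = _bin_means(np.asarray(f), np.asarray(t), edges)
        per_run.append(m)
        counts += c
    stack = np.vstack(per_run)
    import warnings as _warnings
    with _warnings.catch_warnings(), np.errstate(invalid="ignore"):
        _warnings.simplefilter("ignore", RuntimeWarning)   # all-empty bins
        mean = np.nanmean(stack, axis=0)
        std = np.nanstd(stack, axis=0) if len(runs) > 1 else np.zeros_like(mean)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(centers, mean, std, counts, counts == 0)


def vessel_centerline_samples(net, values: dict, theta_interp,
                              step: float | None = None
                              ) -> tuple[np.ndarray, np.ndarray]:
    """(value, theta) pairs sampled along segment center lines."""
    vals, thetas = [], []
    for a, b, d in net.segments():
        length, direction = net.segment_geometry(a, b)
        ds = step or net.lattice.spacing / 2.0
        n = max(2, int(np.ceil(length / ds)))
        pa = net.lattice.position(a)
        for t in np.linspace(0.0, 1.0, n):
            p = pa + t * length * direction
            vals.append(values[(a, b)])
            thetas.append(theta_interp(p))
    return np.asarray(vals), np.asarray(thetas)


# --------------------------------------------------------------------------
# distance-to-vessel profiles and exponential fits
# --------------------------------------------------------------------------

@dataclass
class ExponentialFit:
    amplitude: float
    length: float                # decay length ell (µm)
    length_stderr: float
    degenerate: bool             # flat/unfittable profile


def distance_to_vessels(grid: Grid, vessel_fraction: np.ndarray,
                        threshold: float = 1e-3) -> np.ndarray:
    """Signed distance (µm) from the vascularized region (negative inside)."""
    mask = vessel_fraction > threshold
    if not np.any(mask):
        raise ValueError("no vessel voxels above threshold")
    if np.all(mask):
        return -grid.h * np.ones(grid.shape)
    d_out = ndimage.distance_transform_edt(~mask, sampling=grid.h)
    d_in = ndimage.distance_transform_edt(mask, sampling=grid.h)
    return d_out - d_in


def fit_exponential(distance: np.ndarray, values: np.ndarray,
                    bin_width: float = 15.0) -> ExponentialFit:
    """Least-squares fit A exp(-d/ell) to the positive-distance bin means."""
    d = np.asarray(distance).ravel()
    v = np.asarray(values).ravel()
    sel = d > 0
    if sel.sum() < 4:
        return ExponentialFit(np.nan, np.nan, np.nan, True)
    edges = np.arange(0.0, d[sel].max() + bin_width, bin_width)
    means, counts = _bin_means(v[sel], d[sel], edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = counts > 0
    x, y = centers[ok], means[ok]
    if len(x) < 3 or np.all(y <= 0) or np.ptp(y) < 1e-12 * max(np.max(np.abs(y)), 1e-30):
        return ExponentialFit(float(np.mean(y)) if len(y) else np.nan,
                              np.inf, np.nan, True)
    try:
        popt, pcov = optimize.curve_fit(
            lambda xx, a, ell: a * np.exp(-xx / ell), x, y,
            p0=[float(y[0]), max(float(x[-1]) / 3.0, bin_width)],
            maxfev=10000)
    except RuntimeError:
        return ExponentialFit(np.nan, np.nan, np.nan, True)
    err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    return ExponentialFit(float(popt[0]), float(popt[1]), err, False)


def distance_to_vessel_profile(grid: Grid, field: np.ndarray,
                               vessel_fraction: np.ndarray,
                               threshold: float = 1e-3,
                               bin_width: float = 15.0
                               ) -> tuple[RadialProfile, ExponentialFit]:
    d = distance_to_vessels(grid, vessel_fraction, threshold)
    prof = theta_profile([(field, d)], bin_width=bin_width)
    fit = fit_exponential(d, field, bin_width)
    return prof, fit


# --------------------------------------------------------------------------
# region summaries
# --------------------------------------------------------------------------

@dataclass
class RegionSummary:
    table: pd.DataFrame          # region x (mean, std) per run + ensemble rows


REGIONS = ("viable", "boundary", "interior")


def region_masks(theta: np.ndarray, viable: np.ndarray,
                 boundary_halfwidth: float = 100.0) -> dict[str, np.ndarray]:
    """Viable tumor, boundary shell (|theta|<w) and interior (theta<-w)."""
    v = viable & (theta < 0)
    return {
        "viable": v,
        "boundary": np.abs(theta) < boundary_halfwidth,
        "interior": v & (theta < -boundary_halfwidth),
    }


def region_summaries(maps_by_run: list[dict[str, np.ndarray]],
                     masks_by_run: list[dict[str, np.ndarray]]) -> RegionSummary:
    """Spatial mean/STD per region per run, then ensemble aggregates."""
    rows = []
    for i, (maps, masks) in enumerate(zip(maps_by_run, masks_by_run)):
        for metric, m in maps.items():
            for region, mask in masks.items():
                if not np.any(mask):
                    raise ValueError(f"empty region {region!r} in run {i}")
                rows.append(dict(run=i, metric=metric, region=region,
                                 mean=float(np.mean(m[mask])),
                                 std=float(np.std(m[mask]))))
    df = pd.DataFrame(rows)
    ens = (df.groupby(["metric", "region"])[["mean", "std"]]
           .agg(["mean", "std"]).reset_index())
    ens.columns = ["metric", "region", "mean", "mean_ens_std",
                   "spatial_std", "spatial_std_ens_std"]
    return RegionSummary(ens)


# --------------------------------------------------------------------------
# Table-3-style aggregates
# --------------------------------------------------------------------------

def fluid_aggregates(grid: Grid, sources: SourceField, theta: np.ndarray,
                     tumor_blood_inflow: float | None = None) -> dict[str, float]:
    """Region-integrated fluid budget (µm³/s) plus tumor volume and r_Gamma."""
    vol = grid.cell_volume
    tumor = theta < 0
    normal = ~tumor
    out = {
        "tumor_volume_um3": float(np.sum(tumor) * vol),
        "tumor_volume_fraction": float(np.mean(tumor)),
        "if_influx_tumor": float(np.sum(sources.vessel_in[tumor]) * vol),
        "if_uptake_tumor": float(np.sum((sources.vessel_out
                                         + sources.lymph_out)[tumor]) * vol),
        "if_influx_normal": float(np.sum(sources.vessel_in[normal]) * vol),
        "if_uptake_normal": float(np.sum((sources.vessel_out
                                          + sources.lymph_out)[normal]) * vol),
    }
    if tumor_blood_inflow is not None:
        out["tumor_blood_inflow"] = tumor_blood_inflow
        out["extravasation_ratio"] = (
            out["if_influx_tumor"] / tumor_blood_inflow
            if tumor_blood_inflow > 0 else np.inf)
    return out
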