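"""HDF5 serialization of networks and continuum snapshots, CSV mirrors.

The HDF5 layout holds a ``nodes`` table (id, lattice index, pressure,
boundary tag) and a ``segments`` table (node ids, radius, maturity,
flags) per network group, plus named datasets for continuum fields with
grid metadata; every file embeds the configuration hash and seed for
provenance.
"""

from __future__ import annotations

import hashlib
import json

import h5py
import numpy as np
import pandas as pd

from .continuum import ContinuumState
from .grid import Grid
from .lattice import Lattice, VesselNetwork
from .params import Parameters

_BC_CODE = {None: 0, "arterial": 1, "venous": 2}
_BC_NAME = {v: k for k, v in _BC_CODE.items()}


def config_hash(params: Parameters) -> str:
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def network_tables(net: VesselNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    nodes = list(net.graph.nodes)
    nid = {s: i for i, s in enumerate(nodes)}
    ndf = pd.DataFrame({
        "id": np.arange(len(nodes)),
        **{f"i{k}": [s[k] for s in nodes] for k in range(net.lattice.ndim)},
        "press": [net.graph.nodes[s].get("press", np.nan) for s in nodes],
        "bc": [_BC_CODE[net.graph.nodes[s].get("bc")] for s in nodes],
    })
    rows = []
    for a, b, d in net.graph.edges(data=True):
        rows.append(dict(node_a=nid[a], node_b=nid[b], r=d["r"], w=d["w"],
                         q=d.get("q", 0.0), f=d.get("f", 0.0),
                         htc=d.get("htc", 0.45),
                         sprout=int(d.get("sprout", False)),
                         tumor=int(d.get("tumor", False)),
                         perfused=int(d.get("perfused", False)),
                         capillary=int(d.get("capillary", False)),
                         sprout_age_h=d.get("sprout_age_h", 0.0),
                         time_in_tumor_h=d.get("time_in_tumor_h", 0.0)))
    sdf = pd.DataFrame(rows)
    return ndf, sdf


def save_network(h5: h5py.Group, net: VesselNetwork) -> None:
    ndf, sdf = network_tables(net)
    grp = h5.require_group("network")
    for key in list(grp.keys()):
        del grp[key]
    grp.attrs["spacing"] = net.lattice.spacing
    grp.attrs["extent"] = net.lattice.extent
    grp.attrs["kind"] = net.lattice.kind
    g1 = grp.create_group("nodes")
    for col in ndf.columns:
        g1.create_dataset(col, data=ndf[col].to_numpy())
    g2 = grp.create_group("segments")
    for col in (sdf.columns if len(sdf) else []):
        g2.create_dataset(col, data=sdf[col].to_numpy())


def load_network(h5: h5py.Group) -> VesselNetwork:
    grp = h5["network"]
    lat = Lattice(extent=tuple(int(e) for e in grp.attrs["extent"]),
                  spacing=float(grp.attrs["spacing"]),
                  kind=str(grp.attrs["kind"]))
    net = VesselNetwork(lat)
    nd = grp["nodes"]
    n = len(nd["id"])
    sites = [tuple(int(nd[f"i{k}"][i]) for k in range(lat.ndim))
             for i in range(n)]
    for i, s in enumerate(sites):
        net.add_node(s, bc=_BC_NAME[int(nd["bc"][i])],
                     press=float(nd["press"][i]))
    if "segments" in grp and len(grp["segments"].keys()):
        sd = grp["segments"]
        m = len(sd["node_a"])
        for i in range(m):
            net.add_segment(
                sites[int(sd["node_a"][i])], sites[int(sd["node_b"][i])],
                r=float(sd["r"][i]), w=float(sd["w"][i]),
                q=float(sd["q"][i]), f=float(sd["f"][i]),
                htc=float(sd["htc"][i]),
                sprout=bool(sd["sprout"][i]), tumor=bool(sd["tumor"][i]),
                perfused=bool(sd["perfused"][i]),
                capillary=bool(sd["capillary"][i]),
                sprout_age_h=float(sd["sprout_age_h"][i]),
                time_in_tumor_h=float(sd["time_in_tumor_h"][i]))
    return net


def save_state(h5: h5py.Group, state: ContinuumState) -> None:
    grp = h5.require_group("continuum")
    for key in list(grp.keys()):
        del grp[key]
    grp.attrs["h"] = state.grid.h
    grp.attrs["origin"] = state.grid.origin
    grp.attrs["ecm_fraction"] = state.ecm_fraction
    for name in ("theta", "phi_T", "phi_N", "phi_D", "c", "g"):
        grp.create_dataset(name, data=getattr(state, name))


def load_state(h5: h5py.Group) -> ContinuumState:
    grp = h5["continuum"]
    theta = grp["theta"][...]
    grid = Grid(shape=theta.shape, h=float(grp.attrs["h"]),
                origin=tuple(float(o) for o in grp.attrs["origin"]))
    return ContinuumState(
        grid, theta, grp["phi_T"][...], grp["phi_N"][...], grp["phi_D"][...],
        ecm_fraction=float(grp.attrs["ecm_fraction"]),
        c=grp["c"][...], g=grp["g"][...])


def save_run(path: str, params: Parameters, net: VesselNetwork | None = None,
             state: ContinuumState | None = None,
             extra: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash(params)
        f.attrs["seed"] = params.seed
        f.attrs["config_json"] = json.dumps(params.to_dict())
        if net is not None:
            save_network(f, net)
        if state is not None:
            save_state(f, state)
        if extra:
            g = f.require_group("extra")
            for k, v in extra.items():
                g.create_dataset(k, data=np.asarray(v))


def export_network_csv(net: VesselNetwork, nodes_path: str,
                       segments_path: str) -> None:
    ndf, sdf = network_tables(net)
    ndf.to_csv(nodes_path, index=False)
    sdf.to_csv(segments_path, index=False)
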