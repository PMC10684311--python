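"""Serialization: spikes, weights, maps, connectivity and configs.

Everything is plain text: spikes as two-column TSV (display_id, time_ms),
weight matrices as MatrixMarket sparse files with a JSON index, lattice
maps as CSV grids with a JSON metadata sidecar, connectivity as edge lists,
and simulation configs as YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import scipy.io as sio
import scipy.sparse as sp
import yaml

from .engine import SimulationConfig, SimulationResult
from .maps import SpatialScalarMap, homogeneous_map, hotspot_map
from .network import E_SIDE, I_SIDE, InterModuleWiring
from .stdp import STDPParams
from .synapses import NoiseParams, SynapseParams

__all__ = [
    "write_spikes", "read_spikes", "write_weights", "read_weights",
    "write_map", "read_map", "write_edge_list",
    "config_to_yaml", "config_from_yaml", "save_result",
]


def write_spikes(path, result_or_arrays) -> None:
    """Spike record as TSV: 1-based display id and time in ms."""
    if isinstance(result_or_arrays, SimulationResult):
        ids = result_or_arrays.spike_display_ids
        times = result_or_arrays.spike_times
    else:
        ids, times = result_or_arrays
    arr = np.stack([np.asarray(ids, dtype=float),
                    np.asarray(times, dtype=float)], axis=1)
    np.savetxt(path, arr, fmt=["%d", "%.6f"], delimiter="\t",
               header="display_id\ttime_ms", comments="")


def read_spikes(path):
    """Read a spike TSV back into (display_ids, times_ms)."""
    arr = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if arr.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    return arr[:, 0].astype(np.int64), arr[:, 1]


def write_weights(path, w: np.ndarray, mask: np.ndarray | None = None) -> None:
    """Dense weight matrix as a MatrixMarket sparse file.

    Wired edges with weight exactly zero are kept in the sparsity pattern
    via an explicit mask so round-tripping preserves the graph.
    """
    w = np.asarray(w, dtype=float)
    if mask is None:
        mat = sp.coo_array(w)
    else:
        r, c = np.nonzero(mask)
        mat = sp.coo_array((w[r, c], (r, c)), shape=w.shape)
    sio.mmwrite(str(path), mat)


def read_weights(path, shape=(400, 400)):
    """Read a MatrixMarket weight file into (dense_weights, mask)."""
    mat = sio.mmread(str(path)).tocoo()
    w = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    w[mat.row, mat.col] = mat.data
    mask[mat.row, mat.col] = True
    return w, mask


def write_edge_list(path, w: np.ndarray, mask: np.ndarray) -> None:
    """(source, target, weight) rows for the wired edges, tab-delimited."""
    r, c = np.nonzero(mask)
    arr = np.stack([r.astype(float), c.astype(float), w[r, c]], axis=1)
    np.savetxt(path, arr, fmt=["%d", "%d", "%.9f"], delimiter="\t",
               header="source\ttarget\tweight", comments="")


def write_map(path_csv, smap: SpatialScalarMap, *, sidecar=True) -> None:
    """E-lattice values as a 20 x 20 CSV grid plus I values and metadata.

    The sidecar JSON (``<path>.json``) carries the I-lattice 10 x 10 grid
    and the construction metadata (centers, radius, bounds, steepness).
    """
    np.savetxt(path_csv, smap.e_grid(), delimiter=",", fmt="%.6f")
    if sidecar:
        side = Path(str(path_csv) + ".json")
        payload = {
            "metadata": smap.metadata,
            "i_grid": smap.i_values.reshape(I_SIDE, I_SIDE).tolist(),
        }
        side.write_text(json.dumps(payload, indent=1))


def read_map(path_csv) -> SpatialScalarMap:
    e_grid = np.loadtxt(path_csv, delimiter=",")
    side = Path(str(path_csv) + ".json")
    meta, i_vals = {}, None
    if side.exists():
        payload = json.loads(side.read_text())
        meta = payload.get("metadata", {})
        i_vals = np.asarray(payload["i_grid"]).ravel()
    if i_vals is None:
        # subsample the E grid at even coordinates as the overlay value
        i_vals = e_grid[::2, ::2].ravel()
    return SpatialScalarMap(e_grid.ravel(), i_vals, metadata=meta)


def _map_to_spec(value) -> dict:
    if isinstance(value, SpatialScalarMap):
        meta = value.metadata
        if meta.get("kind") == "homogeneous":
            return {"homogeneous": meta["value"]}
        if meta.get("kind") == "hotspot" and not meta.get("inverted"):
            return {"hotspot": {k: meta[k] for k in
                    ("centers", "radius", "value_min", "value_max",
                     "steepness")}}
        return {"values": {"e": value.e_values.tolist(),
                           "i": value.i_values.tolist()}}
    return {"homogeneous": float(value)}


def _map_from_spec(spec) -> SpatialScalarMap:
    if not isinstance(spec, dict):
        return homogeneous_map(float(spec))
    if "homogeneous" in spec:
        return homogeneous_map(float(spec["homogeneous"]))
    if "hotspot" in spec:
        h = spec["hotspot"]
        return hotspot_map(h["centers"], r=h["radius"],
                           value_min=h["value_min"],
                           value_max=h["value_max"],
                           steepness=h.get("steepness", 1.0))
    if "values" in spec:
        return SpatialScalarMap(np.asarray(spec["values"]["e"]),
                                np.asarray(spec["values"]["i"]))
    raise ValueError(f"unrecognized map spec: {spec!r}")


def config_to_yaml(config: SimulationConfig, path=None) -> str:
    """Serialize a config to YAML (returned; also written when ``path``)."""
    doc = {
        "gks": {m: _map_to_spec(config.gks[m]) for m in (1, 2)},
        "dc": {m: _map_to_spec(config.dc[m]) for m in (1, 2)},
        "intermodule": {"mode": config.intermodule_mode,
                        "in_degree": config.intermodule_in_degree},
        "noise": asdict(config.noise),
        "stdp": asdict(config.stdp),
        "stdp_enabled": config.stdp_enabled,
        "synapse": asdict(config.synapse),
        "dt": config.dt,
        "duration": config.duration,
        "n_trials": config.n_trials,
        "seed": config.seed,
        "method": config.method,
        "dc_to_i_cells": config.dc_to_i_cells,
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_from_yaml(source) -> SimulationConfig:
    """Load a config from a YAML string or file path."""
    p = Path(str(source))
    text = p.read_text() if p.exists() else str(source)
    doc = yaml.safe_load(text)
    inter = doc.get("intermodule", {})
    return SimulationConfig(
        gks={m: _map_from_spec(doc["gks"][m]) for m in (1, 2)},
        dc={m: _map_from_spec(doc["dc"][m]) for m in (1, 2)},
        intermodule_mode=inter.get("mode", "random"),
        intermodule_in_degree=inter.get("in_degree", 40),
        noise=NoiseParams(**doc.get("noise", {})),
        stdp=STDPParams(**doc.get("stdp", {})),
        stdp_enabled=doc.get("stdp_enabled", True),
        synapse=SynapseParams(**doc.get("synapse", {})),
        dt=doc.get("dt", 0.05),
        duration=doc.get("duration", 5000.0),
        n_trials=doc.get("n_trials", 4),
        seed=doc.get("seed", 0),
        method=doc.get("method", "rk4"),
        dc_to_i_cells=doc.get("dc_to_i_cells", False),
    )


def save_result(out_dir, result: SimulationResult) -> None:
    """Write a full result bundle (spikes, weights, metadata) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_spikes(out / "spikes.tsv", result)
    for name, w, mask in [
        ("w_1to2_initial", result.wiring_initial.w_1to2,
         result.wiring_initial.mask_1to2),
        ("w_2to1_initial", result.wiring_initial.w_2to1,
         result.wiring_initial.mask_2to1),
        ("w_1to2_final", result.wiring_final.w_1to2,
         result.wiring_final.mask_1to2),
        ("w_2to1_final", result.wiring_final.w_2to1,
         result.wiring_final.mask_2to1),
    ]:
        write_weights(out / f"{name}.mtx", w, mask)
    if result.weight_snapshots:
        index = []
        for k, (t, w12, w21) in enumerate(result.weight_snapshots):
            for tag, w, mask in (("1to2", w12, result.wiring_final.mask_1to2),
                                 ("2to1", w21, result.wiring_final.mask_2to1)):
                name = f"snapshot_{k:04d}_{tag}.mtx"
                write_weights(out / name, w, mask)
            index.append({"index": k, "time_ms": t})
        (out / "snapshots.json").write_text(json.dumps(index, indent=1))
    meta = {
        "seed_info": result.seed_info,
        "n_spikes": int(len(result.spike_times)),
        "duration_ms": result.config.duration,
    }
    (out / "run.json").write_text(json.dumps(meta, indent=1))
    config_to_yaml(result.config, out / "config.yaml")
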