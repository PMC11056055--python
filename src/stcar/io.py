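"""CSV and JSON interchange: adjacency matrices, panels, and posterior draws."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import SpatialGraph
from .mcmc import PosteriorDraws
from .simulate import SimulatedPanel


def write_adjacency_csv(graph: SpatialGraph, path, ids=None) -> None:
    """Square 0/1 adjacency with a header row of unit IDs."""
    ids = list(ids) if ids is not None else [f"u{i}" for i in range(graph.N)]
    pd.DataFrame(graph.W.astype(int), columns=ids).to_csv(path, index=False)


def read_adjacency_csv(path) -> tuple[SpatialGraph, list[str]]:
    """Read and validate a square adjacency CSV; returns (graph, unit ids)."""
    df = pd.read_csv(path)
    return SpatialGraph(df.to_numpy(dtype=float)), list(df.columns)


def read_edge_list_csv(path, ids=None) -> tuple[SpatialGraph, list[str]]:
    """Two-column edge list of unit IDs; undirected, deduplicated."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("edge list needs two ID columns")
    a, b = df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)
    if ids is None:
        ids = sorted(set(a) | set(b))
    index = {u: i for i, u in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)))
    for u, v in zip(a, b):
        i, j = index[u], index[v]
        if i == j:
            raise ValueError(f"self-loop on unit {u!r}")
        W[i, j] = W[j, i] = 1.0
    return SpatialGraph(W), list(ids)


def write_panel_csv(panel: SimulatedPanel, path) -> None:
    """Long-format panel CSV (unit_id, time, y, offset, x1..xp) + JSON sidecar."""
    path = Path(path)
    N, T = panel.y.shape
    p = panel.X.shape[2]
    unit = np.repeat(np.arange(N), T)
    time = np.tile(np.arange(1, T + 1), N)
    cols = {
        "unit_id": [f"u{i}" for i in unit],
        "time": time,
        "y": panel.y.ravel(),
        "offset": panel.offset.ravel(),
    }
    Xf = panel.X.reshape(N * T, p)
    for j in range(p):
        cols[f"x{j + 1}"] = Xf[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)
    sc = panel.scenario
    sidecar = {
        "sp": sc.sp, "tm": sc.tm, "n_units": sc.n_units, "n_times": sc.n_times,
        "seed": sc.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_panel_csv(path):
    """Read a long-format panel CSV back into (y, offset, X, unit_ids)."""
    df = pd.read_csv(path)
    units = df["unit_id"].drop_duplicates().tolist()
    times = sorted(df["time"].unique())
    N, T = len(units), len(times)
    df = df.set_index(["unit_id", "time"]).sort_index()
    xcols = [c for c in df.columns if c.startswith("x")]
    y = np.zeros((N, T), dtype=np.int64)
    offset = np.zeros((N, T))
    X = np.zeros((N, T, len(xcols)))
    for i, u in enumerate(units):
        block = df.loc[u]
        y[i] = block["y"].to_numpy()
        offset[i] = block["offset"].to_numpy()
        X[i] = block[xcols].to_numpy()
    return y, offset, X, units


def write_draws_csv(draws: PosteriorDraws, path) -> None:
    """Columnar draws CSV (one row per retained draw) + JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame(draws.draws, columns=draws.param_names).to_csv(path, index=False)
    cfg = draws.config
    meta = {
        "n_total": cfg.n_total, "burn_in": cfg.burn_in, "thin": cfg.thin,
        "seed": cfg.seed, "sampler": cfg.sampler,
        "accept_rate": draws.accept_rate, "n_divergent": draws.n_divergent,
        "step_size": draws.step_size,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
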