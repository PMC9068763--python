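"""Serialization: model JSON files, time-series CSV, edge lists, GraphML.

Conventions: CSV time series have one row per time point and one column per
channel, with a header of channel labels; an optional leading integer
``trial`` column separates trials.  Model files are JSON with the sparse
coefficients as ``[lag, row, col, value]`` quadruples; all user-facing
indices (rows, columns, channel numbers in edge lists) are 1-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .granger import CGCMatrix
from .var_core import BlockPartition, SparseVARModel, TimeSeries

__all__ = [
    "save_model",
    "load_model",
    "read_timeseries",
    "write_timeseries",
    "write_edges",
    "read_edges",
    "write_graphml",
]


def save_model(model: SparseVARModel, path) -> None:
    """Write a model as JSON; round-trips losslessly (17 significant
    digits via the shortest-repr float encoding)."""
    coeffs = []
    for lag in sorted(model.coeffs):
        A = model.coeffs[lag].tocoo()
        for r, c, v in zip(A.row, A.col, A.data):
            coeffs.append([int(lag), int(r) + 1, int(c) + 1, float(v)])
    doc = {
        "k": model.k,
        "lags": list(model.lags),
        "coeffs": coeffs,
        "sigma": [[float(x) for x in row] for row in model.sigma],
        "labels": list(model.channel_labels),
        "partition": [[i + 1 for i in b] for b in model.partition.blocks],
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> SparseVARModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed model JSON in {path}: {exc}") from exc
    for field in ("k", "lags", "coeffs", "sigma"):
        if field not in doc:
            raise ValueError(f"model file {path} is missing field {field!r}")
    k = int(doc["k"])
    sigma = np.asarray(doc["sigma"], float)
    if sigma.shape != (k, k):
        raise ValueError(
            f"field 'sigma' has shape {sigma.shape}, expected ({k}, {k})")
    coeffs: dict[int, list] = {}
    for lag, r, c, v in doc["coeffs"]:
        if not (1 <= r <= k and 1 <= c <= k):
            raise ValueError(f"field 'coeffs' has index out of range: {(lag, r, c)}")
        coeffs.setdefault(int(lag), []).append((int(r) - 1, int(c) - 1, float(v)))
    mats = {}
    for lag, triples in coeffs.items():
        rows, cols, vals = zip(*triples)
        mats[lag] = sp.csr_matrix((vals, (rows, cols)), shape=(k, k))
    partition = None
    if doc.get("partition"):
        partition = BlockPartition(
            tuple(tuple(i - 1 for i in b) for b in doc["partition"]))
    return SparseVARModel(
        k=k, lags=tuple(doc["lags"]), coeffs=mats, sigma=sigma,
        partition=partition, channel_labels=tuple(doc.get("labels") or ()))


def read_timeseries(path, sampling_rate: float = 1.0) -> TimeSeries:
    """Read a CSV (rows = time, columns = channels, header = labels); a
    leading integer ``trial`` column splits the file into trials."""
    df = pd.read_csv(path)
    if df.columns[0].strip().lower() == "trial":
        trials = []
        for _, sub in df.groupby(df.columns[0], sort=True):
            trials.append(sub.iloc[:, 1:].to_numpy(float).T)
        labels = tuple(df.columns[1:])
    else:
        trials = [df.to_numpy(float).T]
        labels = tuple(df.columns)
    return TimeSeries(tuple(trials), labels, sampling_rate)


def write_timeseries(ts: TimeSeries, path) -> None:
    frames = []
    for t, trial in enumerate(ts.trials):
        df = pd.DataFrame(trial.T, columns=list(ts.channel_labels))
        if ts.n_trials > 1:
            df.insert(0, "trial", t + 1)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_edges(cgc: CGCMatrix, path) -> None:
    """CSV edge list (source, target, weight, pvalue), 1-based channel
    numbers, zero-weight edges omitted."""
    rows = []
    k = cgc.values.shape[0]
    for i in range(k):       # target
        for j in range(k):   # source
            w = cgc.values[i, j]
            if w > 0:
                p = cgc.pvalues[i, j] if cgc.pvalues is not None else np.nan
                rows.append((j + 1, i + 1, w, p))
    pd.DataFrame(rows, columns=["source", "target", "weight", "pvalue"]).to_csv(
        path, index=False)


def read_edges(path, k: int | None = None) -> CGCMatrix:
    df = pd.read_csv(path)
    if df.duplicated(["source", "target"]).any():
        raise ValueError(f"duplicate edges in {path}")
    if k is None:
        k = int(max(df["source"].max(), df["target"].max())) if len(df) else 0
    V = np.zeros((k, k))
    P = np.ones((k, k))
    for _, row in df.iterrows():
        V[int(row["target"]) - 1, int(row["source"]) - 1] = row["weight"]
        if np.isfinite(row.get("pvalue", np.nan)):
            P[int(row["target"]) - 1, int(row["source"]) - 1] = row["pvalue"]
    return CGCMatrix(V, P)


def write_graphml(cgc: CGCMatrix, path) -> None:
    import networkx as nx

    G = nx.DiGraph()
    labels = cgc.labels
    G.add_nodes_from(labels)
    k = cgc.values.shape[0]
    for i in range(k):
        for j in range(k):
            if cgc.values[i, j] > 0:
                G.add_edge(labels[j], labels[i], weight=float(cgc.values[i, j]))
    nx.write_graphml(G, path)
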