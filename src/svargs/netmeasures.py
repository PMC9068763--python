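"""Weighted-directed network measures on a CGC adjacency matrix.

A functional-connectivity network is the weighted digraph whose adjacency
``W[i, j]`` is the causality strength of the edge i -> j.  The measures
follow the conventions customary for weighted connectivity matrices
(Rubinov & Sporns): path lengths use the distance ``1 / weight``,
unreachable pairs contribute zero efficiency, clustering uses cube-root
weights normalised by the maximum weight, and the binary measures operate
on the thresholded pattern ``W > threshold``.

Everything is computed directly on numpy arrays / scipy shortest paths so
that networkx (and brute-force enumeration) can serve as an independent
cross-check in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

import networkx as nx

__all__ = [
    "WeightedDigraph",
    "scalar_measures",
    "nodal_measures",
    "binary_measures",
]


@dataclass
class WeightedDigraph:
    """Nonnegative weight matrix with zero diagonal; ``W[i, j]`` is the
    weight of the directed edge i -> j."""

    weights: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.any(W < 0) or not np.all(np.isfinite(W)):
            raise ValueError("weights must be finite and nonnegative")
        if np.any(np.diag(W) != 0):
            raise ValueError("self-loops are not allowed")
        self.weights = W.copy()
        if not self.labels:
            self.labels = tuple(f"n{i + 1}" for i in range(W.shape[0]))

    @classmethod
    def from_cgc(cls, cgc) -> "WeightedDigraph":
        return cls(cgc.to_adjacency(), cgc.labels)

    @property
    def k(self) -> int:
        return self.weights.shape[0]

    def to_networkx(self) -> nx.DiGraph:
        G = nx.DiGraph()
        G.add_nodes_from(range(self.k))
        r, c = np.nonzero(self.weights)
        G.add_weighted_edges_from(
            (int(i), int(j), float(self.weights[i, j])) for i, j in zip(r, c))
        return G


def _distance_matrix(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with length = 1/weight."""
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, 0.0)
    return dijkstra(csr_matrix(L), directed=True)


def _triangle_terms(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fagiolo weighted-directed triangle count t_i and its denominator.

    Weights are scaled by the maximum weight before the cube root; the
    denominator is ``d_tot (d_tot - 1) - 2 d_bi`` on the binary pattern.
    """
    mx = W.max()
    Wn = W / mx if mx > 0 else W
    C = np.cbrt(Wn)
    Csym = C + C.T
    t = np.diag(Csym @ Csym @ Csym) / 2.0
    A = (W > 0).astype(float)
    d_tot = A.sum(0) + A.sum(1)
    d_bi = np.diag(A @ A)
    denom = d_tot * (d_tot - 1) - 2 * d_bi
    return t, denom


def _assortativity(W: np.ndarray, x: str, y: str) -> float:
    """Pearson correlation, over directed edges (i, j), of the ``x``
    weighted degree (strength) of the source with the ``y`` weighted
    degree of the target; each edge counts once."""
    deg = {"out": W.sum(1), "in": W.sum(0)}
    r, c = np.nonzero(W)
    if r.size < 2:
        return float("nan")
    xs = deg[x][r]
    ys = deg[y][c]
    vx = np.var(xs)
    vy = np.var(ys)
    if vx <= 0 or vy <= 0:
        return float("nan")
    cov = np.mean((xs - xs.mean()) * (ys - ys.mean()))
    return float(cov / np.sqrt(vx * vy))


def scalar_measures(g: WeightedDigraph) -> dict[str, float]:
    """Whole-network summary measures.

    Returns edge count, matrix density ``edges / k(k-1)``, characteristic
    path length (mean shortest 1/weight distance over ordered reachable
    pairs; NaN when none), global efficiency (mean of 1/distance over all
    ordered pairs, unreachable = 0), weighted transitivity, and the four
    directed assortativities.
    """
    W = g.weights
    k = g.k
    if k < 2:
        raise ValueError("network measures need at least 2 nodes")
    edges = int(np.count_nonzero(W))
    D = _distance_matrix(W)
    off = ~np.eye(k, dtype=bool)
    finite = np.isfinite(D) & off
    cpl = float(D[finite].mean()) if finite.any() else float("nan")
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(D > 0, D, np.inf), 0.0)
    geff = float(inv[off].sum() / (k * (k - 1)))
    t, denom = _triangle_terms(W)
    tsum = denom.sum()
    transitivity = float(t.sum() / tsum) if tsum > 0 else 0.0
    out = {
        "edge_count": float(edges),
        "density": edges / (k * (k - 1)),
        "char_path_length": cpl,
        "global_efficiency": geff,
        "transitivity": transitivity,
    }
    for x in ("in", "out"):
        for y in ("in", "out"):
            out[f"assortativity_{x}_{y}"] = _assortativity(W, x, y)
    return out


def _closeness(D: np.ndarray) -> np.ndarray:
    """Wasserman-Faust closeness from a distance matrix: for node i with
    r reachable peers, ``(r / (k-1)) * (r / sum of distances)``."""
    k = D.shape[0]
    out = np.zeros(k)
    for i in range(k):
        d = np.delete(D[i], i)
        reach = np.isfinite(d)
        r = int(reach.sum())
        if r > 0:
            out[i] = (r / (k - 1)) * (r / d[reach].sum())
    return out


def _principal_eigvec(M: np.ndarray, tol: float = 1e-10,
                      max_iter: int = 10_000) -> np.ndarray:
    """Power iteration for the Perron vector of a nonnegative matrix,
    L2-normalised."""
    k = M.shape[0]
    x = np.full(k, 1.0 / np.sqrt(k))
    for _ in range(max_iter):
        y = M @ x
        nrm = np.linalg.norm(y)
        if nrm == 0:
            return np.zeros(k)
        y /= nrm
        if np.linalg.norm(y - x) < tol:
            return y
        x = y
    return x


def nodal_measures(g: WeightedDigraph,
                   community: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Per-node weighted measures.

    ``community`` is an integer label per node for the participation
    coefficients; the default single community makes participation 0.
    Closeness-total and local efficiency are computed on conventions
    documented inline (there is no single standard for directed variants).
    """
    W = g.weights
    k = g.k
    s_in = W.sum(0)
    s_out = W.sum(1)
    D = _distance_matrix(W)
    t, denom = _triangle_terms(W)
    with np.errstate(invalid="ignore", divide="ignore"):
        clustering = np.where(denom > 0, t / np.where(denom > 0, denom, 1), 0.0)

    if community is None:
        community = np.zeros(k, dtype=int)
    community = np.asarray(community)
    part_in = np.zeros(k)
    part_out = np.zeros(k)
    for m in np.unique(community):
        mask = community == m
        part_out += np.where(s_out > 0, (W[:, mask].sum(1) / np.where(s_out > 0, s_out, 1)) ** 2, 0)
        part_in += np.where(s_in > 0, (W[mask, :].sum(0) / np.where(s_in > 0, s_in, 1)) ** 2, 0)
    participation_out = np.where(s_out > 0, 1 - part_out, 0.0)
    participation_in = np.where(s_in > 0, 1 - part_in, 0.0)

    # local efficiency: global efficiency of the subgraph induced by the
    # union neighbourhood of each node (node excluded)
    local_eff = np.zeros(k)
    A = W > 0
    for i in range(k):
        nb = np.where(A[i] | A[:, i])[0]
        nb = nb[nb != i]
        if nb.size < 2:
            continue
        Dsub = _distance_matrix(W[np.ix_(nb, nb)])
        off = ~np.eye(nb.size, dtype=bool)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(Dsub) & off, 1.0 / Dsub, 0.0)
        local_eff[i] = inv[off].sum() / (nb.size * (nb.size - 1))

    # betweenness via Brandes on 1/weight lengths (raw path counts)
    G = g.to_networkx()
    for (u, v, d) in G.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    btw = nx.betweenness_centrality(G, weight="length", normalized=False)
    betweenness = np.array([btw[i] for i in range(k)])

    subgraph = np.diag(expm((W > 0).astype(float)))

    return {
        "strength_in": s_in,
        "strength_out": s_out,
        "strength_total": s_in + s_out,
        "local_efficiency": local_eff,
        "participation_in": participation_in,
        "participation_out": participation_out,
        "clustering": clustering,
        "closeness_in": _closeness(D.T),
        "closeness_out": _closeness(D),
        "closeness_total": _closeness(_distance_matrix(W + W.T)),
        "eigenvector_in": _principal_eigvec(W.T),
        "eigenvector_out": _principal_eigvec(W),
        "subgraph_centrality": subgraph,
        "betweenness": betweenness,
    }


def binary_measures(g: WeightedDigraph, threshold: float = 0.0,
                    ) -> dict[str, np.ndarray]:
    """Measures on the binarised pattern ``W > threshold``.

    Flow paths of a node v count ordered pairs (i, j), i != j, with edges
    i -> v and v -> j; the flow coefficient divides by nb(nb-1) over the
    union neighbourhood nb of v.  Coreness is the k-core level of the
    underlying (union) undirected pattern from iterative peeling, so a
    complete digraph has coreness k - 1 at every node.
    """
    A = (g.weights > threshold).astype(int)
    k = g.k
    deg_in = A.sum(0)
    deg_out = A.sum(1)

    flow_paths = np.zeros(k, dtype=float)
    flow_coef = np.zeros(k)
    for v in range(k):
        preds = np.where(A[:, v])[0]
        succs = np.where(A[v, :])[0]
        paths = sum(1 for i in preds for j in succs if i != j)
        flow_paths[v] = paths
        nb = np.union1d(preds, succs)
        nb = nb[nb != v]
        if nb.size > 1:
            flow_coef[v] = paths / (nb.size * (nb.size - 1))

    # k-core peeling on the union undirected pattern
    coreness = np.zeros(k, dtype=float)
    alive = np.ones(k, dtype=bool)
    U = ((A + A.T) > 0).astype(int)
    for c in range(1, k + 1):
        while True:
            deg = U.sum(0)
            peel = alive & (deg < c)
            if not peel.any():
                break
            alive &= ~peel
            U[peel, :] = 0
            U[:, peel] = 0
        if not alive.any():
            break
        coreness[alive] = c

    return {
        "degree_in": deg_in.astype(float),
        "degree_out": deg_out.astype(float),
        "degree_total": (deg_in + deg_out).astype(float),
        "flow_coefficient": flow_coef,
        "flow_path_count": flow_paths,
        "coreness": coreness,
    }
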