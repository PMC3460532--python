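"""Graph metrics on weighted SL networks: density, clustering, modularity.

Networks are symmetric nonnegative weight matrices with zero diagonal
(equivalently per-sample SL edge vectors).  Density is the mean
off-diagonal weight; the clustering coefficient is the Onnela
geometric-mean weighted variant normalized by degree-preserving rewired
null networks (weights carried with edges); modularity is the weighted
Newman-Girvan Q of the best partition found by greedy multilevel (Louvain)
optimization over several restarts.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities, modularity

from .sl import SLTensor

__all__ = [
    "density",
    "weighted_clustering",
    "clustering_norm",
    "rewire_preserving_degree",
    "modularity_opt",
    "metric_series",
]


def _check_network(net: np.ndarray) -> np.ndarray:
    net = np.asarray(net, dtype=float)
    if net.ndim != 2 or net.shape[0] != net.shape[1]:
        raise ValueError("network must be a square matrix")
    if not np.allclose(net, net.T):
        raise ValueError("network must be symmetric")
    if net.min() < 0:
        raise ValueError("weights must be nonnegative")
    return net


def density(net: np.ndarray) -> float:
    """Global average weight: mean of the off-diagonal upper triangle."""
    net = _check_network(net)
    iu, ju = np.triu_indices(net.shape[0], 1)
    return float(net[iu, ju].mean())


def weighted_clustering(net: np.ndarray) -> float:
    """Onnela weighted clustering coefficient, averaged over nodes.

    Weights are scaled by the maximum weight; node intensity is the sum of
    geometric means of triangle weights; nodes with binary degree < 2
    contribute 0.
    """
    w = _check_network(net).copy()
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    if wmax == 0:
        raise ValueError("empty network has no clustering coefficient")
    cube = np.linalg.matrix_power(np.cbrt(w / wmax), 3)
    triangles = np.diag(cube)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    c = np.zeros(w.shape[0])
    mask = denom > 0
    c[mask] = triangles[mask] / denom[mask]
    return float(c.mean())


def rewire_preserving_degree(
    net: np.ndarray, rng: np.random.Generator, n_swap_factor: int = 10
) -> np.ndarray:
    """Degree-preserving double-edge swaps, with weights carried by edges.

    A swap replaces edges (a,b),(c,d) by (a,d),(c,b) when this creates no
    self-loop or multi-edge; each surviving edge keeps its weight.  The
    binary degree sequence is preserved exactly.
    """
    net = _check_network(net)
    iu, ju = np.triu_indices(net.shape[0], 1)
    nz = net[iu, ju] > 0
    edges = list(zip(iu[nz].tolist(), ju[nz].tolist()))
    weights = net[iu, ju][nz].tolist()
    existing = set(edges)
    n_edges = len(edges)
    if n_edges < 2:
        return net.copy()
    attempts = n_swap_factor * n_edges
    for _ in range(attempts):
        e1, e2 = rng.choice(n_edges, 2, replace=False)
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if a == d or c == b or new1 in existing or new2 in existing:
            continue
        existing.discard(edges[e1])
        existing.discard(edges[e2])
        edges[e1], edges[e2] = new1, new2
        existing.add(new1)
        existing.add(new2)
    out = np.zeros_like(net)
    for (a, b), w in zip(edges, weights):
        out[a, b] = out[b, a] = w
    return out


def clustering_norm(
    net: np.ndarray, n_null: int = 20, seed: int | np.random.Generator = 0
) -> float:
    """Weighted clustering normalized by degree-preserving rewired nulls.

    Returns C / <C_null>; NaN (with a warning) for an empty network.
    """
    net = _check_network(net)
    if (net > 0).sum() == 0:
        warnings.warn("empty network: normalized clustering undefined", stacklevel=2)
        return float("nan")
    rng = np.random.default_rng(seed)
    c = weighted_clustering(net)
    null = [
        weighted_clustering(rewire_preserving_degree(net, rng))
        for _ in range(n_null)
    ]
    mean_null = float(np.mean(null))
    if mean_null == 0:
        return float("nan")
    return c / mean_null


def _to_graph(net: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(net.shape[0]))
    iu, ju = np.triu_indices(net.shape[0], 1)
    nz = net[iu, ju] > 0
    g.add_weighted_edges_from(
        zip(iu[nz].tolist(), ju[nz].tolist(), net[iu, ju][nz].tolist())
    )
    return g


def modularity_opt(
    net: np.ndarray, n_restarts: int = 10, seed: int | np.random.Generator = 0
) -> tuple[float, np.ndarray]:
    """Best weighted Newman-Girvan modularity over Louvain restarts.

    Returns (Q, labels).  Q is never below the trivial single-module
    partition's value of 0.  Raises on a zero-weight network.
    """
    net = _check_network(net)
    if net.sum() == 0:
        raise ValueError("zero-weight network has no module structure")
    g = _to_graph(net)
    rng = np.random.default_rng(seed)
    best_q, best_part = 0.0, [set(range(net.shape[0]))]
    for _ in range(max(1, n_restarts)):
        part = louvain_communities(g, weight="weight", seed=int(rng.integers(2**31)))
        q = modularity(g, part, weight="weight")
        if q > best_q:
            best_q, best_part = q, part
    labels = np.empty(net.shape[0], dtype=int)
    for cid, comm in enumerate(best_part):
        for node in comm:
            labels[node] = cid
    return float(best_q), labels


def metric_series(
    tensor: SLTensor,
    n_null: int = 20,
    n_restarts: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-valid-sample density, normalized clustering and modularity Q.

    Computed on the (typically FDR-masked) tensor; samples whose network is
    empty get density 0 and NaN clustering/modularity.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(tensor.n_valid):
        net = tensor.as_matrix(t)
        dens = density(net)
        if net.sum() == 0:
            clu, q = float("nan"), float("nan")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clu = clustering_norm(net, n_null=n_null, seed=rng)
            q, _ = modularity_opt(net, n_restarts=n_restarts, seed=rng)
        rows.append((t, dens, clu, q))
    return pd.DataFrame(
        rows, columns=["sample", "density", "clustering_norm", "modularity"]
    )
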