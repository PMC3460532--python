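"""Network similarity over time and edge communities.

The per-sample SL vectors of an epoch form a time series of networks.  Two
views of their joint structure: (1) the T x T cosine-similarity matrix
between all pairs of SL vectors, whose diagonal block structure marks
quasi-stable network states and whose off-diagonal hot patches mark state
recurrences; (2) communities of *edges* whose SL time courses are mutually
correlated, found by modularity maximization on the zero-lag edge-by-edge
correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import modularity_opt
from .sl import SLTensor

__all__ = [
    "SimilarityMatrix",
    "EdgeCommunityPartition",
    "cosine_similarity_matrix",
    "edge_communities",
]


@dataclass
class SimilarityMatrix:
    """Symmetric T x T similarity between per-sample SL vectors."""

    values: np.ndarray
    zero_rows: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class EdgeCommunityPartition:
    """Edge -> community assignment; constant edges live in a silent community."""

    labels: np.ndarray
    edge_index: list[tuple[int, int]]
    silent_community: int | None = None

    @property
    def n_communities(self) -> int:
        return int(np.unique(self.labels).size)


def cosine_similarity_matrix(t: SLTensor | np.ndarray) -> SimilarityMatrix:
    """Cosine similarity between every pair of per-sample SL vectors.

    sim(u, v) = u.v / (|u||v|); for nonnegative SL vectors values lie in
    [0, 1].  Zero-norm samples get similarity 0 to all others and 1 to
    themselves, and are flagged in ``zero_rows``.
    """
    x = t.values if isinstance(t, SLTensor) else np.asarray(t, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 sample vectors")
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    unit = x / safe[:, None]
    sim = unit @ unit.T
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.fill_diagonal(sim, 1.0)
    np.clip(sim, -1.0, 1.0, out=sim)
    return SimilarityMatrix(values=sim, zero_rows=zero)


def edge_communities(
    t: SLTensor | np.ndarray,
    n_restarts: int = 10,
    seed: int = 0,
) -> EdgeCommunityPartition:
    """Communities of co-fluctuating edges.

    Zero-lag Pearson correlations between edge time series are computed,
    negative entries floored at 0 (single-layer modularity assumes
    nonnegative weights), and the resulting weighted graph is clustered by
    greedy multilevel modularity maximization.  Edges with zero temporal
    variance are assigned to a designated silent community.
    """
    if isinstance(t, SLTensor):
        x = t.values
        edge_index = t.edge_index
    else:
        x = np.asarray(t, dtype=float)
        edge_index = [(0, e) for e in range(x.shape[1])]
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 time samples")
    sd = x.std(axis=0)
    scale = max(1.0, float(np.abs(x).max()))
    active = sd > 1e-12 * scale  # tolerate float noise on constant edges
    labels = np.full(x.shape[1], -1, dtype=int)
    silent = None
    n_active = int(active.sum())
    if n_active >= 2:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(x[:, active], rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        np.clip(corr, 0.0, 1.0, out=corr)
        np.fill_diagonal(corr, 0.0)
        if corr.sum() > 0:
            _, sub = modularity_opt(corr, n_restarts=n_restarts, seed=seed)
        else:
            sub = np.arange(n_active)
        labels[active] = sub
    elif n_active == 1:
        labels[active] = 0
    if (~active).any():
        silent = int(labels.max() + 1)
        labels[~active] = silent
    return EdgeCommunityPartition(
        labels=labels, edge_index=list(edge_index), silent_community=silent
    )
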