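"""Independent brute-force reference implementations used as test oracles.

These are deliberately naive (loops, exhaustive enumeration) and share no
code with the package's vectorized implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_sl_tensor(data: np.ndarray, l: int, m: int, w1: int, w2: int, n_rec: int):
    """O(T * W * m) per-sample SL for every channel pair, straight from the
    definition: embed, scan all window candidates, take the n_rec nearest
    (ties by temporal proximity then index), count joint recurrences."""
    n_ch, n = data.shape
    span = (m - 1) * l
    first = w2 - 1
    last = n - span - w2  # inclusive, 0-based
    pairs = list(itertools.combinations(range(n_ch), 2))
    values = []
    for i in range(first, last + 1):
        rec_sets = []
        for k in range(n_ch):
            ref = np.array([data[k, i + a * l] for a in range(m)])
            cands = []
            for j in range(n):
                d = abs(i - j)
                if not (w1 < d < w2):
                    continue
                if j + span >= n or j < 0:
                    continue
                vec = np.array([data[k, j + a * l] for a in range(m)])
                dist = float(np.sqrt(((ref - vec) ** 2).sum()))
                cands.append((dist, d, j))
            cands.sort()
            rec_sets.append({j for _, _, j in cands[:n_rec]})
        values.append(
            [len(rec_sets[a] & rec_sets[b]) / n_rec for a, b in pairs]
        )
    return np.array(values), first


def set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1 :]
        yield [[first]] + smaller


def partitions_as_labels(n: int):
    """All partitions of range(n) as normalized label arrays."""
    for part in set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for cid, block in enumerate(sorted(part, key=min)):
            for i in block:
                labels[i] = cid
        yield labels


def brute_force_best_partition(data: np.ndarray, fitness, k_min=2, k_max=None):
    """Exhaustively maximize ``fitness(labels, data)`` over all partitions."""
    n = data.shape[0]
    k_max = k_max or n
    best, best_fit = None, -np.inf
    for labels in partitions_as_labels(n):
        k = labels.max() + 1
        if not (k_min <= k <= k_max):
            continue
        f = fitness(labels, data)
        if f > best_fit:
            best, best_fit = labels.copy(), f
    return best, best_fit


def newman_girvan_q(w: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman-Girvan modularity from the definition."""
    total = w.sum()  # 2m for an undirected weight matrix
    if total == 0:
        return 0.0
    strength = w.sum(axis=1)
    q = 0.0
    for a in range(w.shape[0]):
        for b in range(w.shape[0]):
            if labels[a] == labels[b]:
                q += w[a, b] / total - strength[a] * strength[b] / total**2
    return q


def brute_force_best_modularity(w: np.ndarray):
    """Exhaustive modularity maximization over all node partitions."""
    n = w.shape[0]
    best, best_q = None, -np.inf
    for labels in partitions_as_labels(n):
        q = newman_girvan_q(w, labels)
        if q > best_q:
            best, best_q = labels.copy(), q
    return best, best_q


def bh_stepup(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up on one family, from the definition."""
    m = len(pvals)
    order = np.argsort(pvals)
    keep = np.zeros(m, dtype=bool)
    kmax = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * q / m:
            kmax = rank
    for rank, idx in enumerate(order, start=1):
        if rank <= kmax:
            keep[idx] = True
    return keep
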