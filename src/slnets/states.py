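"""Evolutionary clustering of SL vectors into temporally coherent network states.

Per-sample SL network vectors are partitioned into clusters by a genetic
algorithm maximizing a Dunn-index variant (minimum between-cluster centroid
separation over maximum mean within-cluster distance-to-centroid).  The
population is seeded from hierarchical clusterings at random cluster
numbers and linkage functions; variation uses crossover (exchange of a
contiguous time window of assignments), point mutation, a temporal "jitter"
operator that expands, contracts or shifts contiguous sub-clusters by one
sample, and a steady influx of freshly seeded immigrants; the fittest
individuals survive unchanged (elitism).  Maximal runs of constant cluster
label define network states with boundaries, durations, and mean-SL
representative vectors; because states can recur, their number typically
exceeds the number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .sl import SLTensor

__all__ = [
    "Partition",
    "NetworkState",
    "EvoConfig",
    "dunn_fitness",
    "seed_population",
    "jitter",
    "crossover",
    "mutate",
    "merge_nearest",
    "absorb_short_runs",
    "refine_boundaries",
    "evolve",
    "extract_states",
    "duration_distribution",
    "DurationSummary",
]


def _normalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters as contiguous integers in order of first appearance."""
    _, norm = np.unique(labels, return_inverse=True)
    first = {}
    out = np.empty_like(labels)
    nxt = 0
    for i, lab in enumerate(norm):
        if lab not in first:
            first[lab] = nxt
            nxt += 1
        out[i] = first[lab]
    return out


@dataclass(frozen=True)
class Partition:
    """Per-sample cluster labels, contiguous integers starting at 0."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = _normalize_labels(np.asarray(self.labels, dtype=int))
        object.__setattr__(self, "labels", labels)

    @property
    def k(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def n_samples(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class EvoConfig:
    """Evolutionary-clustering configuration.

    The desk-scale defaults (pop_size=30, generations=200) keep single-epoch
    segmentation interactive; ``full_scale()`` returns the full-scale
    configuration (population 50, 1500 generations, 5 elites, 25 seed
    cluster numbers from 2..100).  Selection is binary tournament; operator
    rates and the immigrant fraction are implementation choices surfaced
    here.
    """

    pop_size: int = 30
    generations: int = 200
    elite: int = 5
    n_seed_cluster_numbers: int = 25
    max_clusters: int = 100
    mutation_rate: float = 0.3
    crossover_rate: float = 0.3
    jitter_rate: float = 0.3
    merge_rate: float = 0.3
    immigrant_fraction: float = 0.1
    min_cluster_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.elite >= self.pop_size:
            raise ValueError("elite must be smaller than pop_size")
        for r in (
            self.mutation_rate,
            self.crossover_rate,
            self.jitter_rate,
            self.merge_rate,
            self.immigrant_fraction,
        ):
            if not (0 <= r <= 1):
                raise ValueError("rates must lie in [0, 1]")

    @classmethod
    def full_scale(cls, seed: int = 0) -> "EvoConfig":
        return cls(pop_size=50, generations=1500, seed=seed)


def dunn_fitness(
    p: Partition | np.ndarray, data: np.ndarray, min_cluster_size: int = 1
) -> float:
    """Dunn-variant fitness: min centroid separation / max mean within-distance.

    Higher is better.  A partition whose clusters are all point masses
    (zero denominator) is degenerate and scores 0; k < 2 is an error.
    With ``min_cluster_size`` > 1, clusters below that size are excluded
    from the separation term (a guard against a bulk-plus-far-outlier
    optimum on heavy-noise data; note that it also makes excising noisy
    samples into micro-clusters profitable, so it is off by default — the
    all-pairs minimum already punishes micro-clusters through their tiny
    separation from their parent cluster).  If fewer than two clusters
    reach the minimum size, the partition scores 0.
    """
    labels = p.labels if isinstance(p, Partition) else np.asarray(p, dtype=int)
    data = np.asarray(data, dtype=float)
    k = int(labels.max()) + 1
    if k < 2:
        raise ValueError("a partition must have at least 2 clusters")
    counts = np.bincount(labels, minlength=k).astype(float)
    sums = np.zeros((k, data.shape[1]))
    np.add.at(sums, labels, data)
    centroids = sums / counts[:, None]
    member_d = np.linalg.norm(data - centroids[labels], axis=1)
    within = np.bincount(labels, weights=member_d, minlength=k) / counts
    denom = within.max()
    if denom == 0:
        return 0.0
    eligible = np.nonzero(counts >= min_cluster_size)[0]
    if eligible.size < 2:
        return 0.0
    sep = cdist(centroids[eligible], centroids[eligible])
    between = sep[np.triu_indices(eligible.size, 1)].min()
    return float(between / denom)


def _safe_fitness(
    labels: np.ndarray, data: np.ndarray, min_cluster_size: int = 1
) -> float:
    if labels.max() < 1:
        return 0.0
    return dunn_fitness(labels, data, min_cluster_size)


def _seed_pool(
    data: np.ndarray, cfg: EvoConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Hierarchical partitions at random cluster numbers and three linkages."""
    t = data.shape[0]
    hi = min(cfg.max_clusters, t - 1)
    numbers = rng.choice(
        np.arange(2, hi + 1),
        size=min(cfg.n_seed_cluster_numbers, hi - 1),
        replace=False,
    )
    pool = []
    for method in ("single", "average", "complete"):
        z = linkage(data, method=method, metric="euclidean")
        for n_clust in numbers:
            pool.append(fcluster(z, t=int(n_clust), criterion="maxclust") - 1)
    return pool


def _repair(labels: np.ndarray) -> np.ndarray:
    """Ensure k >= 2 by splitting the largest cluster at its temporal midpoint."""
    labels = _normalize_labels(labels)
    if labels.max() >= 1:
        return labels
    idx = np.arange(labels.size)
    half = idx[labels.size // 2 :]
    labels = labels.copy()
    labels[half] = 1
    return labels


def _seed_member(
    pool: list[np.ndarray], t: int, rng: np.random.Generator
) -> np.ndarray:
    """Build one population member by unioning random clusters from the pool."""
    out = np.full(t, -1, dtype=int)
    nxt = 0
    while (out < 0).any():
        part = pool[rng.integers(len(pool))]
        clusters = np.unique(part)
        c = clusters[rng.integers(clusters.size)]
        members = (part == c) & (out < 0)
        if members.any():
            out[members] = nxt
            nxt += 1
    return _repair(out)


def seed_population(data: np.ndarray, cfg: EvoConfig) -> list[Partition]:
    """Seed an initial population from hierarchical clustering runs.

    25 cluster numbers are drawn without replacement from 2..100 (capped at
    T - 1); each is clustered with single, average and complete linkage to
    form a pool of partitions; each member repeatedly adopts a random
    cluster from a random pool partition until every sample is assigned.
    Members ending with fewer than 2 clusters are repaired by splitting the
    largest cluster at its temporal midpoint.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 4:
        raise ValueError("need at least 4 samples to seed a population")
    rng = np.random.default_rng(cfg.seed)
    pool = _seed_pool(data, cfg, rng)
    return [
        Partition(_seed_member(pool, data.shape[0], rng))
        for _ in range(cfg.pop_size)
    ]


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (start, end_inclusive, label)."""
    out = []
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            out.append((start, i - 1, int(labels[start])))
            start = i
    return out


def jitter(
    p: Partition, seed: int | np.random.Generator = 0
) -> tuple[Partition, bool]:
    """Apply one temporal jitter move to a random contiguous run.

    Moves: expand (neighbours adopt the run's label), contract (the run's
    two outermost samples become fresh singleton clusters), or shift (one
    boundary expands while the other contracts, moving the run one sample).
    Epoch boundaries truncate moves.  Returns (partition, applied); a
    partition without any run of length >= 2 is returned unchanged.
    """
    rng = np.random.default_rng(seed)
    labels = p.labels.copy()
    eligible = [r for r in _runs(labels) if r[1] - r[0] >= 1]
    if not eligible:
        return p, False
    start, end, lab = eligible[rng.integers(len(eligible))]
    move = rng.integers(3)
    fresh = labels.max() + 1
    if move == 0:  # expand
        if start - 1 >= 0:
            labels[start - 1] = lab
        if end + 1 < labels.size:
            labels[end + 1] = lab
    elif move == 1:  # contract
        labels[start] = fresh
        labels[end] = fresh + 1
    else:  # shift by one sample
        if rng.random() < 0.5:  # forward
            labels[start] = fresh
            if end + 1 < labels.size:
                labels[end + 1] = lab
        else:  # backward
            labels[end] = fresh
            if start - 1 >= 0:
                labels[start - 1] = lab
    return Partition(labels), True


def crossover(
    p1: Partition, p2: Partition, rng: np.random.Generator
) -> Partition:
    """Exchange cluster assignments on a random contiguous time window.

    The receiving partition keeps its labels outside the window and adopts
    the donor's raw labels inside it.  Label ids that occur on both sides
    of the window boundary merge the corresponding clusters — a macro-move
    that lets the search coarsen fragmented partitions quickly.
    """
    t = p1.labels.size
    a, b = np.sort(rng.integers(0, t + 1, size=2))
    if a == b:
        return p1
    child = p1.labels.copy()
    child[a:b] = p2.labels[a:b]
    return Partition(child)


def mutate(
    p: Partition, rng: np.random.Generator, max_clusters: int = 100
) -> Partition:
    """Reassign one random sample to a random existing or fresh cluster."""
    labels = p.labels.copy()
    i = rng.integers(labels.size)
    k = labels.max() + 1
    hi = k + 1 if k < max_clusters else k
    labels[i] = rng.integers(hi)
    return Partition(labels)


def merge_nearest(
    p: Partition, data: np.ndarray, rng: np.random.Generator
) -> Partition:
    """Agglomerate nearest-centroid cluster pairs down to a random count.

    The point mutation, window crossover and jitter moves all act on one or
    a few samples, so they cannot coarsen a heavily fragmented partition
    (e.g. a union of fine hierarchical seeds that over-split a homogeneous
    stretch) within a realistic number of generations; the fitness surface
    between a fragmented partition and the coarse optimum is flat, so
    single-cluster merges only drift.  This macro-move draws a target
    cluster count k' uniformly from [2, k) and repeatedly fuses the pair of
    clusters with nearest (size-weighted) centroids until k' remain —
    preferentially rejoining fragments of the same underlying state, whose
    centroids nearly coincide.
    """
    labels = p.labels
    k = int(labels.max()) + 1
    if k < 3:
        return p
    target_k = int(rng.integers(2, k))
    counts = np.bincount(labels, minlength=k).astype(float)
    sums = np.zeros((k, data.shape[1]))
    np.add.at(sums, labels, data)
    centroids = sums / counts[:, None]
    d = cdist(centroids, centroids)
    np.fill_diagonal(d, np.inf)
    parent = np.arange(k)
    alive = np.ones(k, dtype=bool)
    n_alive = k
    while n_alive > target_k:
        flat = int(d.argmin())
        a, b = divmod(flat, k)
        # fuse b into a (weighted centroid), retire b
        tot = counts[a] + counts[b]
        centroids[a] = (counts[a] * centroids[a] + counts[b] * centroids[b]) / tot
        counts[a] = tot
        parent[b] = a
        alive[b] = False
        d[b, :] = np.inf
        d[:, b] = np.inf
        row = np.linalg.norm(centroids[alive] - centroids[a], axis=1)
        d[a, alive] = row
        d[alive, a] = row
        d[a, a] = np.inf
        n_alive -= 1
    # resolve the union-find chains
    for i in range(k):
        r = i
        while parent[r] != r:
            r = parent[r]
        parent[i] = r
    return Partition(parent[labels])


def evolve(
    data: np.ndarray, cfg: EvoConfig | None = None
) -> tuple[Partition, float]:
    """Evolutionary search for the partition maximizing the Dunn fitness.

    Binary-tournament selection, elitism, crossover/mutation/jitter
    variation and immigrant replacement; returns the best-ever partition
    and its fitness.  generations=0 returns the best of the seeded
    population.  Deterministic given cfg.seed.
    """
    data = np.asarray(data, dtype=float)
    cfg = cfg or EvoConfig()
    rng = np.random.default_rng(cfg.seed)
    t = data.shape[0]
    if t < 4:
        raise ValueError("need at least 4 samples")
    if not np.isfinite(data).all():
        raise ValueError("data must be finite")
    pool = _seed_pool(data, cfg, rng)
    pop = [_seed_member(pool, t, rng) for _ in range(cfg.pop_size)]
    mcs = cfg.min_cluster_size
    fits = np.array([_safe_fitness(m, data, mcs) for m in pop])
    best_i = int(fits.argmax())
    best_labels, best_fit = pop[best_i].copy(), float(fits[best_i])

    def tournament() -> int:
        i, j = rng.integers(cfg.pop_size, size=2)
        return i if fits[i] >= fits[j] else j

    n_breed = cfg.pop_size - cfg.elite
    n_imm = int(round(cfg.immigrant_fraction * n_breed))
    for _ in range(cfg.generations):
        order = np.argsort(fits)[::-1]
        new_pop = [pop[i].copy() for i in order[: cfg.elite]]
        new_fits = [float(fits[i]) for i in order[: cfg.elite]]
        for _ in range(n_breed - n_imm):
            child = Partition(pop[tournament()])
            if rng.random() < cfg.crossover_rate:
                child = crossover(child, Partition(pop[tournament()]), rng)
            if rng.random() < cfg.mutation_rate:
                child = mutate(child, rng, cfg.max_clusters)
            if rng.random() < cfg.merge_rate:
                child = merge_nearest(child, data, rng)
            if rng.random() < cfg.jitter_rate:
                child, _ = jitter(child, rng)
            new_pop.append(child.labels)
            new_fits.append(_safe_fitness(child.labels, data, mcs))
        for _ in range(n_imm):
            imm = _seed_member(pool, t, rng)
            new_pop.append(imm)
            new_fits.append(_safe_fitness(imm, data, mcs))
        pop = new_pop
        fits = np.array(new_fits)
        gen_best = int(fits.argmax())
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_labels = pop[gen_best].copy()
    return Partition(best_labels), best_fit


def refine_boundaries(
    p: Partition,
    data: np.ndarray,
    radius: int = 60,
    sweeps: int = 2,
    min_run: int = 5,
) -> Partition:
    """Greedy local polish of state boundaries.

    The stochastic search settles cluster identities well before it settles
    exact junction positions (the one-sample jitter moves random boundaries
    in random directions).  This finisher scans each junction between
    adjacent runs over ``radius`` positions either side — reassigning the
    intervening samples to the left or right run's label — and keeps the
    position maximizing the Dunn-variant fitness; ``sweeps`` passes are
    made over all junctions.  Moves never shrink either run below
    ``min_run`` samples.  Deterministic; never decreases fitness.
    """
    labels = p.labels.copy()
    best_fit = _safe_fitness(labels, data)
    for _ in range(sweeps):
        moved = False
        runs = _runs(labels)
        for j in range(len(runs) - 1):
            left_lab = labels[runs[j][0]]
            right_lab = labels[runs[j + 1][0]]
            if left_lab == right_lab:
                continue
            b = runs[j][1] + 1  # current junction (first sample of right run)
            lo = max(runs[j][0] + min_run, b - radius)
            hi = min(runs[j + 1][1] - min_run + 1, b + radius)
            for cand in range(lo, hi + 1):
                if cand == b:
                    continue
                trial = labels.copy()
                if cand < b:
                    trial[cand:b] = right_lab
                else:
                    trial[b:cand] = left_lab
                fit = _safe_fitness(_normalize_labels(trial), data)
                if fit > best_fit:
                    best_fit = fit
                    labels = trial
                    moved = True
            runs = _runs(labels)
        if not moved:
            break
    return Partition(labels)


def absorb_short_runs(
    p: Partition, data: np.ndarray, min_samples: int
) -> Partition:
    """Fold temporal runs shorter than ``min_samples`` into a neighbour.

    The SL estimator smears any change in coupling over roughly the
    embedding span, so label runs much shorter than that are flicker below
    the measure's temporal resolution; their single-sample representatives
    are too noisy to classify downstream.  Each short run adopts the label
    of whichever temporally adjacent run has the nearer centroid in
    ``data`` (feature) space; runs are processed shortest-first and the
    procedure iterates until every surviving run has at least
    ``min_samples`` samples or only one run remains.
    """
    if min_samples <= 1:
        return p
    labels = p.labels.copy()
    data = np.asarray(data, dtype=float)
    while True:
        runs = _runs(labels)
        if len(runs) <= 1:
            break
        short = [r for r in runs if r[1] - r[0] + 1 < min_samples]
        if not short:
            break
        start, end, _ = min(short, key=lambda r: (r[1] - r[0], r[0]))
        idx = runs.index((start, end, labels[start]))
        here = data[start : end + 1].mean(axis=0)
        cands = []
        for j in (idx - 1, idx + 1):
            if 0 <= j < len(runs):
                s2, e2, lab2 = runs[j]
                c = data[s2 : e2 + 1].mean(axis=0)
                cands.append((float(np.linalg.norm(here - c)), lab2))
        labels[start : end + 1] = min(cands)[1]
    return Partition(labels)


@dataclass
class NetworkState:
    """A maximal run of contiguous samples sharing one cluster label."""

    cluster: int
    start: int
    end: int
    duration_ms: float
    representative: np.ndarray
    subject: str = ""
    epoch: int = 0
    band: str = ""

    @property
    def n_samples(self) -> int:
        return self.end - self.start + 1


def extract_states(
    p: Partition,
    tensor: SLTensor,
    subject: str = "",
    epoch: int = 0,
    band: str = "",
) -> list[NetworkState]:
    """Run-length encode a partition into network states.

    State boundaries are the samples where the cluster label switches; each
    state's representative is the mean SL vector over its run and its
    duration is run length times the sample period.  States tile the valid
    range without overlap.
    """
    if p.labels.size != tensor.n_valid:
        raise ValueError("partition does not cover the tensor's valid samples")
    states = []
    for start, end, lab in _runs(p.labels):
        states.append(
            NetworkState(
                cluster=lab,
                start=start,
                end=end,
                duration_ms=(end - start + 1) * tensor.sample_period,
                representative=tensor.values[start : end + 1].mean(axis=0),
                subject=subject,
                epoch=epoch,
                band=band,
            )
        )
    return states


@dataclass
class DurationSummary:
    """Empirical distribution of state durations (milliseconds)."""

    durations: np.ndarray
    mean: float
    median: float
    ecdf_x: np.ndarray
    ecdf_f: np.ndarray


def duration_distribution(states: list[NetworkState]) -> DurationSummary:
    """Empirical CDF, mean and median of state durations in ms."""
    if not states:
        raise ValueError("need at least one state")
    d = np.array([s.duration_ms for s in states], dtype=float)
    x = np.sort(d)
    f = np.arange(1, d.size + 1) / d.size
    return DurationSummary(
        durations=d,
        mean=float(d.mean()),
        median=float(np.median(d)),
        ecdf_x=x,
        ecdf_f=f,
    )
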