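"""Network-state repertoire: duration-balanced ensembles, chance-corrected
state similarity, families, and consensus meta-families.

Subjects contribute unequal numbers of states; to remove this sampling bias
the repertoire is characterized over many duration-balanced ensembles.  The
target time is the smallest per-subject total state duration divided by
four; each ensemble samples states uniformly without replacement within
each subject until that subject's sampled duration exceeds the target.
Within an ensemble, the cosine similarity of every state pair is compared
with a null of edge-permuted representative vectors; pairs whose empirical
similarity significantly exceeds the null (one-sample one-tailed t-test)
form a binary graph, whose greedy-modularity communities are the state
families.  Aggregating the family-average topographies of all ensembles and
clustering their similarity matrix yields consensus meta-families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .metrics import modularity_opt
from .states import NetworkState

__all__ = [
    "StateEnsemble",
    "FamilyPartition",
    "build_ensembles",
    "significant_similarity",
    "detect_families",
    "consensus_families",
]


@dataclass
class StateEnsemble:
    """States sampled across subjects with approximately equal total duration."""

    states: list[NetworkState]
    subjects: list[str]
    sampled_totals: dict[str, float]
    target_time: float
    seed: int = 0

    def representatives(self) -> np.ndarray:
        return np.stack([s.representative for s in self.states])


@dataclass
class FamilyPartition:
    """State -> family assignment for one ensemble."""

    labels: np.ndarray
    topographies: np.ndarray  # family x edge mean representative
    flagged_empty: bool = False

    @property
    def n_families(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_families)


def build_ensembles(
    states_by_subject: dict[str, list[NetworkState]],
    n_ensembles: int = 100,
    seed: int = 0,
) -> list[StateEnsemble]:
    """Duration-balanced random ensembles of states.

    target_time = (minimum subject total duration) / 4; per ensemble and
    subject, states are drawn uniformly without replacement until the
    cumulative sampled duration exceeds the target.  Subjects with zero
    total duration are excluded with a warning.
    """
    totals = {
        s: sum(st.duration_ms for st in sts)
        for s, sts in states_by_subject.items()
    }
    empty = [s for s, tot in totals.items() if tot == 0 or not states_by_subject[s]]
    if empty:
        warnings.warn(f"excluding subjects with no states: {empty}", stacklevel=2)
    subjects = [s for s in states_by_subject if s not in empty]
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects with states")
    target = min(totals[s] for s in subjects) / 4.0
    rng = np.random.default_rng(seed)
    out = []
    for e in range(n_ensembles):
        chosen: list[NetworkState] = []
        sampled: dict[str, float] = {}
        for s in subjects:
            order = rng.permutation(len(states_by_subject[s]))
            acc = 0.0
            for i in order:
                st = states_by_subject[s][i]
                chosen.append(st)
                acc += st.duration_ms
                if acc > target:
                    break
            sampled[s] = acc
        out.append(
            StateEnsemble(
                states=chosen,
                subjects=subjects,
                sampled_totals=sampled,
                target_time=target,
                seed=seed,
            )
        )
    return out


def _cosine_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    u = x / safe[:, None]
    sim = u @ u.T
    return sim


def significant_similarity(
    ens: StateEnsemble,
    n_perm: int = 1000,
    alpha: float = 1e-6,
    seed: int = 0,
) -> np.ndarray:
    """Binary state-by-state matrix of above-chance cosine similarity.

    The null for each pair is the similarity after independently permuting
    each representative vector's edge entries, repeated ``n_perm`` times.
    A one-sample, one-tailed t-test of the null sample against the
    empirical similarity (H1: empirical greater than the null mean) marks a
    pair significant when p < alpha.  Pairs involving a constant vector are
    never significant (permutation leaves them unchanged).
    """
    reps = ens.representatives()
    n, n_edges = reps.shape
    if n < 2:
        raise ValueError("need at least 2 states")
    emp = _cosine_rows(reps)
    rng = np.random.default_rng(seed)
    s1 = np.zeros((n, n))
    s2 = np.zeros((n, n))
    for _ in range(n_perm):
        idx = rng.random((n, n_edges)).argsort(axis=1)
        sim = _cosine_rows(np.take_along_axis(reps, idx, axis=1))
        s1 += sim
        s2 += sim**2
    mean = s1 / n_perm
    var = (s2 - n_perm * mean**2) / (n_perm - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = (emp - mean) / np.sqrt(var / n_perm)
    pvals = np.where(
        var > 0,
        spstats.t.sf(tstat, df=n_perm - 1),
        np.where(emp > mean, 0.0, 1.0),
    )
    binary = (pvals < alpha).astype(int)
    scale = max(1.0, float(np.abs(reps).max()))
    constant = reps.std(axis=1) <= 1e-12 * scale
    if constant.any():
        warnings.warn(
            "constant representative vectors: their pairs set to 0", stacklevel=2
        )
        binary[constant, :] = 0
        binary[:, constant] = 0
    np.fill_diagonal(binary, 0)
    binary = binary & binary.T  # enforce symmetry
    return binary


def detect_families(
    binary: np.ndarray, representatives: np.ndarray | None = None,
    n_restarts: int = 10, seed: int = 0,
) -> FamilyPartition:
    """Greedy-modularity communities of the significant-similarity graph.

    An empty graph makes every state its own family (flagged).  If
    ``representatives`` is given, per-family average topographies are
    computed; otherwise they are zero vectors.
    """
    binary = np.asarray(binary)
    n = binary.shape[0]
    if binary.sum() == 0:
        labels = np.arange(n)
        flagged = True
    else:
        _, labels = modularity_opt(
            binary.astype(float), n_restarts=n_restarts, seed=seed
        )
        flagged = False
    # contiguous family ids in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    n_fam = int(labels.max()) + 1
    if representatives is None:
        topo = np.zeros((n_fam, 1))
    else:
        representatives = np.asarray(representatives, dtype=float)
        topo = np.stack(
            [representatives[labels == f].mean(axis=0) for f in range(n_fam)]
        )
    return FamilyPartition(labels=labels, topographies=topo, flagged_empty=flagged)


@dataclass
class ConsensusFamilies:
    """Meta-families over all ensembles' families."""

    meta_of_family: np.ndarray  # one label per (ensemble, family), flattened
    family_ensemble: np.ndarray  # which ensemble each family came from
    family_local_id: np.ndarray  # family id within its ensemble
    topographies: np.ndarray  # meta-family average topographies
    state_fraction: np.ndarray  # fraction of states per meta-family

    @property
    def n_meta(self) -> int:
        return int(self.meta_of_family.max()) + 1


def consensus_families(
    partitions: list[FamilyPartition],
    n_restarts: int = 10,
    seed: int = 0,
    min_similarity: float = 0.0,
) -> ConsensusFamilies:
    """Aggregate families across ensembles into consensus meta-families.

    The family-by-family cosine-similarity matrix over all ensembles'
    family-average topographies is clustered by modularity maximization;
    each meta-family's topography is the mean of its member families', and
    state fractions are the share of all states (over all ensembles)
    falling in each meta-family.  A single ensemble yields the identity
    consensus.
    """
    if not partitions:
        raise ValueError("need at least one ensemble partition")
    topos = np.concatenate([p.topographies for p in partitions], axis=0)
    ens_of = np.concatenate(
        [np.full(p.n_families, e) for e, p in enumerate(partitions)]
    )
    local = np.concatenate([np.arange(p.n_families) for p in partitions])
    sizes = np.concatenate([p.sizes for p in partitions]).astype(float)
    if len(partitions) == 1:
        meta = np.arange(topos.shape[0])
    else:
        sim = _cosine_rows(topos)
        np.fill_diagonal(sim, 0.0)
        sim = np.where(sim > min_similarity, sim, 0.0)
        if sim.sum() == 0:
            meta = np.arange(topos.shape[0])
        else:
            _, meta = modularity_opt(sim, n_restarts=n_restarts, seed=seed)
            _, meta = np.unique(meta, return_inverse=True)
    n_meta = int(meta.max()) + 1
    meta_topo = np.stack([topos[meta == f].mean(axis=0) for f in range(n_meta)])
    frac = np.array(
        [sizes[meta == f].sum() for f in range(n_meta)]
    )
    frac /= frac.sum()
    return ConsensusFamilies(
        meta_of_family=meta,
        family_ensemble=ens_of,
        family_local_id=local,
        topographies=meta_topo,
        state_fraction=frac,
    )
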