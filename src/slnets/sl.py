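"""Synchronization likelihood (SL): time-resolved nonlinear coupling networks.

SL measures generalized synchronization between two channels by counting
coincident recurrences of their time-delay-embedded state vectors.  For a
channel series x and sample i, the state vector is

    X_i = <x_i, x_{i+l}, ..., x_{i+(m-1)l}>

with lag ``l`` and embedding dimension ``m``.  Recurrences of X_i are the
``n_rec`` nearest embedded vectors (Euclidean distance) among candidates j in
a two-sided window  w1 < |i - j| < w2; the window excludes autocorrelated
neighbours (inner edge w1) and bounds the search horizon (outer edge w2).
With J^k the recurrence index set of channel k at sample i, the SL between
channels k1 and k2 at sample i is

    S_i^{k1,k2} = |J^{k1} ∩ J^{k2}| / n_rec ,

the fraction of simultaneous recurrences.  For independent channels the
expected SL is the chance level n_rec / (2 (w2 - w1 - 1)).

Parameters are tied to the band's frequency content: the lag samples the
fastest component about three times per cycle, the embedding spans the
slowest component, the inner window edge skips two embedding spans, and the
outer edge fixes the recurrence density n_rec / (w2 - w1) at a reference
probability p_ref.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import BandSpec, Epoch

__all__ = [
    "SLParams",
    "SLTensor",
    "derive_sl_params",
    "embed",
    "recurrence_set",
    "sl_at_sample",
    "compute_sl_tensor",
    "valid_sample_count",
    "edge_index_pairs",
]


@dataclass(frozen=True)
class SLParams:
    """Embedding and recurrence parameters, all in samples.

    l: embedding lag; m: embedding dimension; w1/w2: inner/outer recurrence
    window edges (strict: candidates satisfy w1 < |i-j| < w2); n_rec: number
    of recurrences kept per reference vector.
    """

    l: int
    m: int
    w1: int
    w2: int
    n_rec: int

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError("lag l must be >= 1")
        if self.m < 2:
            raise ValueError("embedding dimension m must be >= 2")
        if not (0 < self.w1 < self.w2):
            raise ValueError("need 0 < w1 < w2")
        if not (1 <= self.n_rec <= self.n_candidates):
            raise ValueError(
                f"n_rec={self.n_rec} exceeds the {self.n_candidates} candidates "
                f"admitted by the window (w1={self.w1}, w2={self.w2})"
            )

    @property
    def span(self) -> int:
        """Embedding span (m - 1) * l in samples."""
        return (self.m - 1) * self.l

    @property
    def n_candidates(self) -> int:
        """Recurrence candidates per sample: 2 * (w2 - w1 - 1)."""
        return 2 * (self.w2 - self.w1 - 1)

    @property
    def chance_level(self) -> float:
        """Expected SL for independent channels: n_rec / n_candidates."""
        return self.n_rec / self.n_candidates

    def min_epoch_len(self) -> int:
        return self.span + 2 * (self.w2 - 1) + 1


def derive_sl_params(
    band: BandSpec, fs: float, n_rec: int = 10, p_ref: float = 0.05
) -> SLParams:
    """Derive SL parameters from a band's frequency content.

    l = floor(fs / (3 f_high));  m = round(3 f_high / f_low + 1);
    w1 = 2 l (m - 1);  w2 = w1 + n_rec / p_ref - 1.

    For the canonical broadband (4-30 Hz) at 500 Hz this gives l=5, m=24,
    w1=230 samples (460 ms), w2=429 samples (858 ms) with n_rec=10.
    """
    l = int(np.floor(fs / (3.0 * band.f_high)))
    if l < 1:
        raise ValueError(
            f"sampling rate {fs} too low for band edge {band.f_high} Hz"
        )
    m = int(np.floor(3.0 * band.f_high / band.f_low + 1.0 + 0.5))  # round half up
    w1 = 2 * l * (m - 1)
    w2 = w1 + int(round(n_rec / p_ref)) - 1
    return SLParams(l=l, m=m, w1=w1, w2=w2, n_rec=n_rec)


def edge_index_pairs(n_channels: int) -> list[tuple[int, int]]:
    """Ordered channel pairs (k1 < k2) defining the edge axis."""
    return [
        (k1, k2) for k1 in range(n_channels) for k2 in range(k1 + 1, n_channels)
    ]


def valid_sample_count(n_samples: int, p: SLParams) -> int:
    """Number of valid SL samples in an epoch of ``n_samples``.

    Sample i (0-based) is valid iff its own embedding and the embeddings of
    every window candidate fit inside the epoch, i.e.
    i in [w2 - 1, n_samples - span - w2].  A 2500-sample epoch under the
    canonical broadband parameters yields 1529 valid samples.
    """
    n = n_samples - p.span - 2 * (p.w2 - 1)
    if n < 1:
        raise ValueError(
            f"epoch of {n_samples} samples too short for SL parameters "
            f"(needs >= {p.min_epoch_len()})"
        )
    return n


def embed(x: np.ndarray, i: int, l: int, m: int) -> np.ndarray:
    """Time-delay embedding of a single channel at sample i (0-based)."""
    x = np.asarray(x)
    if i < 0 or i + (m - 1) * l >= x.shape[-1]:
        raise IndexError(
            f"embedding at i={i} with span {(m - 1) * l} exceeds the series"
        )
    return x[i : i + (m - 1) * l + 1 : l]


def _all_embeddings(x: np.ndarray, l: int, m: int) -> np.ndarray:
    """All embeddings as an (N - (m-1)l, m) strided view."""
    return sliding_window_view(x, (m - 1) * l + 1)[:, ::l]


def _candidate_offsets(p: SLParams) -> np.ndarray:
    """Signed offsets j - i admitted by the window, in increasing j order."""
    left = np.arange(-(p.w2 - 1), -p.w1)
    right = np.arange(p.w1 + 1, p.w2)
    return np.concatenate([left, right])


def recurrence_set(x: np.ndarray, i: int, p: SLParams) -> np.ndarray:
    """Indices of the n_rec nearest embedded vectors to X_i within the window.

    Candidates are all j with w1 < |i - j| < w2 whose embeddings fit in the
    series.  Ties in distance are broken by smaller |i - j|, then smaller j.
    Returns the chosen j (0-based), sorted ascending.
    """
    x = np.asarray(x, dtype=float)
    offsets = _candidate_offsets(p)
    js = i + offsets
    ok = (js >= 0) & (js + p.span < x.shape[-1])
    js = js[ok]
    if i < 0 or i + p.span >= x.shape[-1]:
        raise IndexError(f"reference embedding at i={i} does not fit")
    if js.size < p.n_rec:
        raise ValueError(
            f"only {js.size} admissible candidates at i={i}, need {p.n_rec}"
        )
    ref = embed(x, i, p.l, p.m)
    cands = _all_embeddings(x, p.l, p.m)[js]
    d2 = ((cands - ref) ** 2).sum(axis=1)
    order = np.lexsort((js, np.abs(js - i), d2))
    return np.sort(js[order[: p.n_rec]])


def sl_at_sample(J1: np.ndarray, J2: np.ndarray, n_rec: int) -> float:
    """SL value from two recurrence index sets: |J1 ∩ J2| / n_rec."""
    J1 = np.asarray(J1)
    J2 = np.asarray(J2)
    if J1.size != n_rec or J2.size != n_rec:
        raise ValueError("recurrence sets must each contain n_rec indices")
    return np.intersect1d(J1, J2).size / n_rec


@dataclass
class SLTensor:
    """Valid-time x edge matrix of SL values for one epoch.

    ``first_valid_index`` is the 0-based offset of the first SL sample into
    the epoch (equal to w2 - 1); ``sample_period`` is in milliseconds.
    """

    values: np.ndarray
    first_valid_index: int
    sample_period: float
    edge_index: list[tuple[int, int]]
    params: SLParams | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.edge_index):
            raise ValueError("values must be valid-time x edge")

    @property
    def n_valid(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return max(max(e) for e in self.edge_index) + 1

    def as_matrix(self, t: int) -> np.ndarray:
        """The symmetric channels x channels SL matrix at valid sample t."""
        k = self.n_channels
        w = np.zeros((k, k))
        for e, (k1, k2) in enumerate(self.edge_index):
            w[k1, k2] = w[k2, k1] = self.values[t, e]
        return w

    def save(self, path: str | Path) -> None:
        """Persist as compressed array + JSON sidecar."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), values=self.values)
        side = {
            "first_valid_index": int(self.first_valid_index),
            "sample_period": float(self.sample_period),
            "edge_index": [list(e) for e in self.edge_index],
            "params": None
            if self.params is None
            else {
                "l": self.params.l,
                "m": self.params.m,
                "w1": self.params.w1,
                "w2": self.params.w2,
                "n_rec": self.params.n_rec,
            },
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(side, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SLTensor":
        path = Path(path)
        values = np.load(path.with_suffix(".npz"))["values"]
        side = json.loads(path.with_suffix(".json").read_text())
        params = side["params"]
        return cls(
            values=values,
            first_valid_index=side["first_valid_index"],
            sample_period=side["sample_period"],
            edge_index=[tuple(e) for e in side["edge_index"]],
            params=None if params is None else SLParams(**params),
            meta=side.get("meta", {}),
        )


def _recurrence_indicators(data: np.ndarray, p: SLParams) -> np.ndarray:
    """Boolean (n_valid, n_channels, n_candidates) recurrence indicators.

    Candidate c of valid sample v refers to epoch sample
    (w2 - 1 + v) + offsets[c]; by validity every candidate's embedding fits,
    so the offset grid is identical for all valid samples.
    """
    n_ch, n = data.shape
    n_valid = valid_sample_count(n, p)
    offsets = _candidate_offsets(p)
    abs_off = np.abs(offsets)
    valid = np.arange(p.w2 - 1, p.w2 - 1 + n_valid)
    ind = np.zeros((n_valid, n_ch, offsets.size), dtype=bool)
    rows = np.arange(n_valid)[:, None]
    for k in range(n_ch):
        emb = _all_embeddings(data[k], p.l, p.m)
        base = emb[valid]
        d2 = np.empty((n_valid, offsets.size))
        for c, off in enumerate(offsets):
            diff = base - emb[valid + off]
            d2[:, c] = np.einsum("ij,ij->i", diff, diff)
        order = np.lexsort(
            (
                np.broadcast_to(offsets, d2.shape),
                np.broadcast_to(abs_off, d2.shape),
                d2,
            ),
            axis=-1,
        )
        ind[rows, k, order[:, : p.n_rec]] = True
    return ind


def compute_sl_tensor(epoch: Epoch | np.ndarray, p: SLParams, fs: float | None = None) -> SLTensor:
    """Compute SL for every channel pair at every valid sample of an epoch.

    The epoch should be band-filtered and standardized with the band matching
    ``p``.  Valid samples are those whose embedding and every window
    candidate's embedding fit inside the epoch; SL at those samples is the
    normalized overlap of the per-channel recurrence sets.
    """
    if isinstance(epoch, Epoch):
        data = epoch.data
        fs = epoch.fs
    else:
        data = np.asarray(epoch, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a channels x samples array with >= 2 channels")
    valid_sample_count(data.shape[1], p)  # raises epoch-too-short
    ind = _recurrence_indicators(data, p)
    f = ind.astype(np.float32)
    counts = np.matmul(f, f.transpose(0, 2, 1))  # (V, K, K) intersection sizes
    k = data.shape[0]
    iu, ju = np.triu_indices(k, 1)
    values = counts[:, iu, ju] / p.n_rec
    return SLTensor(
        values=values.astype(float),
        first_valid_index=p.w2 - 1,
        sample_period=1000.0 / fs,
        edge_index=list(zip(iu.tolist(), ju.tolist())),
        params=p,
    )
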