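"""Surrogate-calibrated edge significance for SL tensors.

The null hypothesis for each edge is that the observed synchronization is
explained by a stationary, linear, possibly cross-correlated Gaussian
process.  Amplitude-adjusted phase-randomized surrogates realize this null:
each channel is rank-remapped onto Gaussian deviates, Fourier transformed,
rotated by a random phase vector *shared across channels* (preserving the
cross-spectrum and hence all linear coupling), inverse transformed, and
mapped back onto its original amplitude distribution.  SL computed on an
ensemble of such surrogates yields per-edge, per-sample null distributions;
a one-tailed Wilcoxon signed-rank test (observed minus surrogate, H1:
median > 0) gives p-values, and a Benjamini-Hochberg step-up within each
sample point controls the false discovery rate across edges.  Non-retained
edge weights are set to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .preprocess import Epoch
from .sl import SLParams, SLTensor, compute_sl_tensor

__all__ = [
    "SurrogateEnsemble",
    "EdgeMask",
    "make_surrogate",
    "surrogate_sl_ensemble",
    "signed_rank_pvalues",
    "edge_pvalues",
    "fdr_mask",
]


def make_surrogate(epoch: Epoch, seed: int | np.random.Generator) -> Epoch:
    """Amplitude-adjusted, phase-randomized surrogate of an epoch.

    The random phase vector is identical for all channels, so linear
    cross-channel correlation is preserved while any nonlinear dependence is
    destroyed.  Each output channel's multiset of values equals the input's
    exactly (the Gaussian rank-remap is inverted at the end).
    """
    rng = np.random.default_rng(seed)
    data = np.asarray(epoch.data, dtype=float)
    k, n = data.shape
    # rank-remap each channel onto a common set of sorted Gaussian deviates
    gauss = np.sort(rng.standard_normal(n))
    ranks = np.argsort(np.argsort(data, axis=1, kind="stable"), axis=1)
    g = gauss[ranks]
    spec = np.fft.rfft(g, axis=1)
    nf = spec.shape[1]
    phases = np.zeros(nf)
    lo, hi = 1, nf - 1 if n % 2 == 0 else nf
    phases[lo:hi] = rng.uniform(0, 2 * np.pi, hi - lo)
    rotated = np.fft.irfft(spec * np.exp(1j * phases)[None, :], n=n, axis=1)
    # invert the Gaussianization: map back onto each channel's own values
    out_ranks = np.argsort(np.argsort(rotated, axis=1, kind="stable"), axis=1)
    sorted_orig = np.sort(data, axis=1)
    surr = np.take_along_axis(sorted_orig, out_ranks, axis=1)
    return Epoch(
        surr,
        fs=epoch.fs,
        band=epoch.band,
        source=epoch.source,
        index=epoch.index,
        standardized=epoch.standardized,
    )


@dataclass
class SurrogateEnsemble:
    """SL values from ``n_surr`` surrogate epochs: (n_surr, valid-time, edge)."""

    values: np.ndarray
    seed: int
    params: SLParams | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("ensemble values must be (n_surr, time, edge)")

    @property
    def n_surr(self) -> int:
        return self.values.shape[0]


def surrogate_sl_ensemble(
    epoch: Epoch, p: SLParams, n_surr: int = 200, seed: int = 0
) -> SurrogateEnsemble:
    """SL tensors for ``n_surr`` independent surrogates of one epoch."""
    rng = np.random.default_rng(seed)
    vals = None
    for s in range(n_surr):
        surr = make_surrogate(epoch, rng)
        t = compute_sl_tensor(surr, p)
        if vals is None:
            vals = np.empty((n_surr,) + t.values.shape, dtype=np.float32)
        vals[s] = t.values
    return SurrogateEnsemble(values=vals, seed=seed, params=p)


def _exact_sf_table(n: int) -> np.ndarray:
    """P(W+ >= w) for the tie-free signed-rank null with n pairs."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    probs = counts / 2.0**n
    return np.cumsum(probs[::-1])[::-1]


def signed_rank_pvalues(diffs: np.ndarray, method: str = "auto") -> np.ndarray:
    """One-tailed Wilcoxon signed-rank p-values along axis 0 (H1: median > 0).

    Vectorized over all trailing axes.  Zeros are handled by the Pratt
    method (ranked, then dropped from the statistic).  ``method``:
    ``"approx"`` uses the normal approximation with tie and continuity
    corrections; ``"exact"`` uses the exact tie-free null distribution (only
    valid for cells without ties or zeros); ``"auto"`` uses the exact law
    for tie-free cells when n <= 50 and the approximation elsewhere.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    flat = diffs.reshape(n, -1)
    absd = np.abs(flat)
    ranks = spstats.rankdata(absd, axis=0, method="average")
    wplus = np.where(flat > 0, ranks, 0.0).sum(axis=0)
    nzero = (flat == 0).sum(axis=0)

    # tie correction: sum over tied groups of (t^3 - t), per column
    s = np.sort(absd, axis=0)
    new_group = np.ones_like(s, dtype=bool)
    new_group[1:] = s[1:] != s[:-1]
    ncols = flat.shape[1]
    gid = np.cumsum(new_group, axis=0) - 1 + np.arange(ncols) * n
    tcounts = np.bincount(gid.ravel("F"), minlength=n * ncols).astype(float)
    tie_term = (tcounts**3 - tcounts).reshape(ncols, n).sum(axis=1)

    mean = n * (n + 1) / 4.0 - nzero * (nzero + 1) / 4.0
    var = (
        n * (n + 1) * (2 * n + 1) / 24.0
        - nzero * (nzero + 1) * (2 * nzero + 1) / 24.0
        - tie_term / 48.0
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (wplus - mean - 0.5) / np.sqrt(var)
    p = np.where(var > 0, spstats.norm.sf(z), 1.0)

    tie_free = (tie_term == 0) & (nzero == 0)
    if method == "exact" and not tie_free.all():
        raise ValueError("exact method requires tie-free, zero-free differences")
    use_exact = (
        tie_free
        if method == "exact"
        else tie_free if (method == "auto" and n <= 50) else np.zeros_like(tie_free)
    )
    if use_exact.any():
        sf = _exact_sf_table(n)
        w_int = np.round(wplus[use_exact]).astype(int)
        p[use_exact] = sf[w_int]
    return np.clip(p, 0.0, 1.0).reshape(diffs.shape[1:])


def edge_pvalues(obs: SLTensor, ens: SurrogateEnsemble, method: str = "auto") -> np.ndarray:
    """Per-edge, per-sample one-tailed signed-rank p-values (observed > null)."""
    if ens.params is not None and obs.params is not None and ens.params != obs.params:
        raise ValueError("ensemble was computed with different SL parameters")
    if ens.values.shape[1:] != obs.values.shape:
        raise ValueError("ensemble and observed tensor shapes do not match")
    if ens.n_surr < 10:
        warnings.warn(
            f"only {ens.n_surr} surrogates: signed-rank test is underpowered",
            stacklevel=2,
        )
    diffs = obs.values[None, :, :] - ens.values.astype(float)
    return signed_rank_pvalues(diffs, method=method)


@dataclass
class EdgeMask:
    """Boolean retention matrix from per-sample FDR control."""

    mask: np.ndarray
    pvalues: np.ndarray
    q: float

    def apply(self, tensor: SLTensor) -> SLTensor:
        """Zero the weights of non-retained edges."""
        if self.mask.shape != tensor.values.shape:
            raise ValueError("mask shape does not match tensor")
        return SLTensor(
            values=np.where(self.mask, tensor.values, 0.0),
            first_valid_index=tensor.first_valid_index,
            sample_period=tensor.sample_period,
            edge_index=tensor.edge_index,
            params=tensor.params,
            meta={**tensor.meta, "fdr_q": self.q},
        )


def fdr_mask(p: np.ndarray, q: float = 1e-4) -> EdgeMask:
    """Benjamini-Hochberg step-up within each sample point (row of ``p``).

    The FDR family is the set of edge p-values at one sample point; each row
    is thresholded at the largest p_(k) with p_(k) <= k q / m.
    """
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    p = np.atleast_2d(np.asarray(p, dtype=float))
    m = p.shape[1]
    ps = np.sort(p, axis=1)
    thresh = q * np.arange(1, m + 1) / m
    ok = ps <= thresh[None, :]
    # cutoff per row: largest passing order statistic, or -inf if none
    kmax = np.where(ok.any(axis=1), m - 1 - np.argmax(ok[:, ::-1], axis=1), -1)
    cutoff = np.where(kmax >= 0, ps[np.arange(p.shape[0]), kmax], -np.inf)
    mask = p <= cutoff[:, None]
    return EdgeMask(mask=mask, pvalues=p, q=q)
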