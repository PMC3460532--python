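"""Synthetic multichannel signals with planted nonlinear coupling states.

Two generators provide ground truth for every downstream stage:

* :func:`gen_coupled_henon` — chains of Hénon maps with tunable diffusive
  coupling, the canonical benchmark for recurrence-based synchronization
  measures.  Coupling strength 1 forces identical trajectories after a
  transient; strength 0 gives independent chaotic series.

* :func:`gen_switching_epoch` — band-limited stochastic oscillations whose
  pairwise *nonlinear* coupling switches between a small set of coupling
  matrices ("planted states") over the epoch, plus additive broadband noise.

Both are deterministic given the schedule seed.  A coupling matrix is
symmetric with zero diagonal and entries in [0, 1]; dynamically the
lower-index channel of each pair drives the higher-index one, so the matrix
encodes undirected coupling strength while the flow of influence is
unidirectional.  (A literally mutual drive cannot reach identical synchrony
at full coupling — the two channels would exchange rather than share state.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import BandSpec, Recording, design_bandpass
from scipy import signal as sps

__all__ = [
    "CouplingSchedule",
    "SyntheticTruth",
    "gen_coupled_henon",
    "gen_switching_epoch",
]


def _check_coupling_matrix(c: np.ndarray, n_channels: int) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if c.shape != (n_channels, n_channels):
        raise ValueError(f"coupling matrix must be {n_channels}x{n_channels}")
    if not np.allclose(c, c.T):
        raise ValueError("coupling matrix must be symmetric")
    if np.any(np.diag(c) != 0):
        raise ValueError("coupling matrix must have zero diagonal")
    if c.min() < 0 or c.max() > 1:
        raise ValueError("coupling strengths must lie in [0, 1]")
    in_w = np.tril(c, -1).sum(axis=1)  # total drive received per channel
    if in_w.max() > 1:
        raise ValueError(
            "total coupling received by a channel must not exceed 1"
        )
    return c


@dataclass
class CouplingSchedule:
    """Ordered (duration_in_samples, coupling_matrix) segments of one epoch."""

    segments: list[tuple[int, np.ndarray]]
    n_channels: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        checked = []
        for dur, c in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            checked.append((int(dur), _check_coupling_matrix(c, self.n_channels)))
        self.segments = checked

    @property
    def total_samples(self) -> int:
        return sum(d for d, _ in self.segments)

    def state_labels(self) -> np.ndarray:
        """Per-sample planted-state id (segment index)."""
        return np.repeat(
            np.arange(len(self.segments)), [d for d, _ in self.segments]
        )


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated recording."""

    state_labels: np.ndarray
    couplings: list[np.ndarray] = field(default_factory=list)


def gen_coupled_henon(
    schedule: CouplingSchedule, fs: float = 500.0, transient: int = 1000
) -> tuple[Recording, SyntheticTruth]:
    """Coupled Hénon maps following a coupling schedule.

    Each channel iterates x <- 1.4 - u^2 + 0.3 y, y <- x, where the drive
    term is u = (1 - c_tot) x + sum_j c_jk x_j over lower-index drivers j.
    At pairwise coupling 1 the response reproduces the driver's quadratic
    term exactly and the pair synchronizes identically after the transient.
    A transient of ``transient`` (>= 1000) iterates under the first
    segment's coupling is discarded.
    """
    transient = max(int(transient), 1000)
    rng = np.random.default_rng(schedule.seed)
    k = schedule.n_channels
    x = 0.1 * rng.standard_normal(k)
    y = 0.1 * rng.standard_normal(k)
    out = np.empty((k, schedule.total_samples))

    def step(x, y, cmat):
        drive = np.tril(cmat, -1)  # drive[k, j] for j < k
        ctot = drive.sum(axis=1)
        u = (1.0 - ctot) * x + drive @ x
        x_new = 1.4 - u**2 + 0.3 * y
        return x_new, x.copy()

    c0 = schedule.segments[0][1]
    for _ in range(transient):
        x, y = step(x, y, c0)
    t = 0
    for dur, cmat in schedule.segments:
        for _ in range(dur):
            x, y = step(x, y, cmat)
            out[:, t] = x
            t += 1
    if not np.isfinite(out).all():
        raise FloatingPointError("Hénon iteration diverged; try another seed")
    rec = Recording(out, fs=fs, labels=[f"henon{j}" for j in range(k)])
    truth = SyntheticTruth(
        state_labels=schedule.state_labels(),
        couplings=[c for _, c in schedule.segments],
    )
    return rec, truth


def _signed_square(u: np.ndarray) -> np.ndarray:
    # monotone quadratic distortion, unit variance for standard-normal input
    return u * np.abs(u) / np.sqrt(3.0)


def _centered_square(u: np.ndarray) -> np.ndarray:
    # even distortion: zero *linear* correlation with the driver
    return (u**2 - 1.0) / np.sqrt(2.0)


_NONLINEARITIES = {
    "signed_square": _signed_square,
    "centered_square": _centered_square,
}


def gen_switching_epoch(
    schedule: CouplingSchedule,
    band: BandSpec,
    fs: float = 500.0,
    noise_sd: float = 0.1,
    nonlinearity: str = "signed_square",
) -> tuple[Recording, SyntheticTruth]:
    """Band-limited oscillations with switching nonlinear coupling.

    Each channel starts from independent Gaussian noise band-passed to
    ``band``.  Within each schedule segment, channel k receives a mixture

        s_k = (1 - c_tot) z_k + sum_{j<k} c_jk g(z_j)

    where g is a static nonlinear distortion of the (filtered) driver.
    Because g plants higher-order dependence rather than a purely linear
    cross-spectrum, the coupling survives phase-randomized surrogate
    testing, which is exactly what downstream significance stages look for.
    Broadband measurement noise of standard deviation ``noise_sd`` (in units
    of the unit-variance oscillation) is added afterwards.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    try:
        g = _NONLINEARITIES[nonlinearity]
    except KeyError:
        raise ValueError(
            f"unknown nonlinearity {nonlinearity!r}; "
            f"expected one of {sorted(_NONLINEARITIES)}"
        ) from None
    rng = np.random.default_rng(schedule.seed)
    k = schedule.n_channels
    n = schedule.total_samples
    taps = design_bandpass(band, fs)
    eps = rng.standard_normal((k, n))
    padlen = min(3 * len(taps), n - 1)
    z = sps.filtfilt(taps, [1.0], eps, axis=1, padtype="even", padlen=padlen)
    z /= z.std(axis=1, keepdims=True)
    gz = g(z)
    out = np.empty_like(z)
    t = 0
    for dur, cmat in schedule.segments:
        drive = np.tril(cmat, -1)
        ctot = drive.sum(axis=1)
        sl_ = slice(t, t + dur)
        out[:, sl_] = (1.0 - ctot)[:, None] * z[:, sl_] + drive @ gz[:, sl_]
        t += dur
    out += noise_sd * rng.standard_normal((k, n))
    rec = Recording(out, fs=fs, labels=[f"syn{j}" for j in range(k)])
    truth = SyntheticTruth(
        state_labels=schedule.state_labels(),
        couplings=[c for _, c in schedule.segments],
    )
    return rec, truth
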