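"""Epoching, downsampling, artifact rejection, band-pass filtering and referencing.

The target pipeline for multichannel resting recordings: continuous data are
cut into fixed-length epochs and decimated to a common rate; epochs with
gross artifacts are discarded on the raw (microvolt-scale) signal; surviving
epochs are band-pass filtered with a zero-phase FIR filter, re-referenced to
the instantaneous channel average, and each channel is standardized to zero
mean and unit variance.  Artifact rules operate on the *unfiltered* signal
because their thresholds are stated in recorded microvolts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

__all__ = [
    "Recording",
    "BandSpec",
    "Epoch",
    "CANONICAL_BANDS",
    "get_band",
    "epoch_and_downsample",
    "reject_artifacts",
    "bandpass_reference_standardize",
]


@dataclass
class Recording:
    """A multichannel time series: ``data`` is channels x samples."""

    data: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] < 2:
            raise ValueError("a Recording needs at least 2 channels")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.labels:
            self.labels = [f"ch{k}" for k in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("number of labels must match number of channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band of interest with pass-band edges in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError("need 0 < f_low < f_high")


#: Canonical analysis bands (Hz).
CANONICAL_BANDS: dict[str, BandSpec] = {
    "broadband": BandSpec("broadband", 4.0, 30.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
}


def get_band(name: str) -> BandSpec:
    try:
        return CANONICAL_BANDS[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; expected one of {sorted(CANONICAL_BANDS)}"
        ) from None


@dataclass
class Epoch:
    """A fixed-length segment of a Recording.

    ``band`` is None for raw (unfiltered) epochs.  ``standardized`` records
    whether channels have been z-scored; several downstream stages require a
    standardized epoch.
    """

    data: np.ndarray
    fs: float
    band: BandSpec | None = None
    source: str = ""
    index: int = 0
    standardized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be channels x samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def epoch_and_downsample(
    rec: Recording, epoch_len_s: float = 5.0, target_fs: float = 500.0
) -> list[Epoch]:
    """Split a recording into consecutive epochs at ``target_fs``.

    The decimation ratio ``rec.fs / target_fs`` must be an integer; an
    anti-alias low-pass (8th-order Chebyshev-I, via :func:`scipy.signal.decimate`)
    is applied before keeping every ``ratio``-th sample.  A trailing partial
    epoch is discarded.
    """
    ratio = rec.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"unsupported rate: fs={rec.fs} is not an integer multiple of "
            f"target_fs={target_fs}"
        )
    ratio = int(round(ratio))
    if ratio == 1:
        data = rec.data
    else:
        data = sps.decimate(rec.data, ratio, axis=1, zero_phase=True)
    n_per = int(round(epoch_len_s * target_fs))
    n_epochs = data.shape[1] // n_per
    return [
        Epoch(
            data[:, e * n_per : (e + 1) * n_per].copy(),
            fs=target_fs,
            index=e,
        )
        for e in range(n_epochs)
    ]


def _epoch_slope(data: np.ndarray) -> np.ndarray:
    """Magnitude of the fitted linear trend (first-to-last sample rise) per channel."""
    n = data.shape[1]
    t = np.arange(n) - (n - 1) / 2.0
    slope = data @ t / (t @ t)  # per-sample slope of least-squares line
    return np.abs(slope) * (n - 1)


def reject_artifacts(
    epochs: list[Epoch],
    amp_limit: float = 200.0,
    slope_limit: float = 75.0,
    z_limit: float = 3.0,
    kurt_z_limit: float = 5.0,
) -> tuple[list[Epoch], list[tuple[Epoch, list[str]]]]:
    """Screen raw epochs for gross artifacts.

    An epoch is rejected if (1) any sample exceeds ``+-amp_limit`` microvolts,
    (2) any channel's fitted linear trend over the epoch exceeds
    ``slope_limit`` microvolts, (3) any channel's mean absolute amplitude is
    more than ``z_limit`` standard deviations from that channel's
    across-epoch mean, or (4) any channel's amplitude kurtosis is more than
    ``kurt_z_limit`` SDs from its across-epoch mean.  Rules 3-4 need at
    least two epochs; with fewer they are skipped with a warning.

    Returns ``(kept, rejected)`` where each rejected entry carries the list
    of triggered rule names.
    """
    reasons: list[list[str]] = [[] for _ in epochs]
    for i, ep in enumerate(epochs):
        if np.abs(ep.data).max() > amp_limit:
            reasons[i].append("amplitude")
        if _epoch_slope(ep.data).max() > slope_limit:
            reasons[i].append("slope")
    if len(epochs) >= 2:
        # across-epoch distributional rules, per channel
        mean_abs = np.stack([np.abs(ep.data).mean(axis=1) for ep in epochs])
        kurt = np.stack(
            [spstats.kurtosis(ep.data, axis=1, fisher=True) for ep in epochs]
        )
        for stat, limit, tag in (
            (mean_abs, z_limit, "distribution"),
            (kurt, kurt_z_limit, "kurtosis"),
        ):
            mu = stat.mean(axis=0)
            sd = stat.std(axis=0, ddof=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.where(sd > 0, (stat - mu) / sd, 0.0)
            for i in range(len(epochs)):
                if np.abs(z[i]).max() > limit:
                    reasons[i].append(tag)
    elif epochs:
        warnings.warn(
            "fewer than 2 epochs: distribution/kurtosis rules skipped",
            stacklevel=2,
        )
    kept = [ep for ep, r in zip(epochs, reasons) if not r]
    rejected = [(ep, r) for ep, r in zip(epochs, reasons) if r]
    return kept, rejected


def design_bandpass(band: BandSpec, fs: float) -> np.ndarray:
    """Zero-phase linear FIR band-pass (Hamming windowed-sinc).

    Transition bands are 25% of each band edge, matching common practice for
    band-limited field-potential analysis.
    """
    trans_lo = 0.25 * band.f_low
    trans_hi = 0.25 * band.f_high
    if band.f_high + trans_hi >= fs / 2:
        raise ValueError(
            f"band {band.name} ({band.f_low}-{band.f_high} Hz) does not fit "
            f"below the Nyquist rate of fs={fs}"
        )
    # filter length: ~3.3 cycles of the narrowest transition (Hamming)
    width = min(trans_lo, trans_hi) / (fs / 2.0)
    numtaps = int(np.ceil(3.3 / width)) | 1  # force odd
    return sps.firwin(
        numtaps,
        [band.f_low - trans_lo / 2, band.f_high + trans_hi / 2],
        pass_zero=False,
        window="hamming",
        fs=fs,
    )


def bandpass_reference_standardize(
    epoch: Epoch, band: BandSpec, average_reference: bool = True
) -> Epoch:
    """Zero-phase band-pass, average reference, per-channel z-scoring.

    The instantaneous mean over channels is subtracted after filtering
    (average reference), then each channel is scaled to zero mean and unit
    variance over the epoch.  A channel with zero variance after referencing
    (e.g. two identical channels in a 2-channel montage) is an error.

    ``average_reference=False`` skips the re-referencing step — appropriate
    for synthetic recordings that carry no physical reference electrode;
    with few channels the subtraction of the channel mean would otherwise
    leak every channel's signal (including planted couplings) into all
    others.
    """
    if epoch.standardized:
        raise ValueError("epoch is already standardized")
    taps = design_bandpass(band, epoch.fs)
    padlen = min(3 * len(taps), epoch.data.shape[1] - 1)
    filtered = sps.filtfilt(
        taps, [1.0], epoch.data, axis=1, padtype="even", padlen=padlen
    )
    if average_reference:
        filtered -= filtered.mean(axis=0, keepdims=True)
    filtered -= filtered.mean(axis=1, keepdims=True)
    sd = filtered.std(axis=1, ddof=0)
    dead = np.nonzero(sd < 1e-12)[0]
    if dead.size:
        raise ValueError(
            f"zero-variance channel(s) after referencing: indices {dead.tolist()}"
        )
    filtered /= sd[:, None]
    return replace(
        epoch, data=filtered, band=band, standardized=True
    )
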