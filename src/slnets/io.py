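"""File I/O: recordings (TSV/CSV/EDF), truth labels, tensors, tables, figures."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Recording
from .sl import SLTensor
from .states import NetworkState
from .synthetic import SyntheticTruth

__all__ = [
    "read_recording",
    "write_recording_tsv",
    "write_truth_tsv",
    "read_truth_tsv",
    "sl_tensor_to_tsv",
    "states_to_table",
    "save_similarity_heatmap",
]


def read_recording(
    path: str | Path, fs: float | None = None, sep: str | None = None
) -> Recording:
    """Read a channels x samples matrix (TSV/CSV) or an EDF file.

    Plain matrices need ``fs``; an optional first column of non-numeric
    channel labels is detected automatically.  EDF files require the
    optional ``mne`` dependency.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:
            raise ImportError(
                "reading EDF requires the optional dependency mne "
                "(pip install slnets[edf])"
            ) from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(
            raw.get_data() * 1e6, fs=float(raw.info["sfreq"]), labels=raw.ch_names
        )
    if fs is None:
        raise ValueError("fs is required for plain-matrix recordings")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, header=None)
    labels: list[str] = []
    first = df.iloc[:, 0]
    if first.dtype == object:
        labels = first.astype(str).tolist()
        df = df.iloc[:, 1:]
    return Recording(df.to_numpy(dtype=float), fs=fs, labels=labels)


def write_recording_tsv(rec: Recording, path: str | Path) -> None:
    """Write a recording as label + samples rows, tab-separated."""
    path = Path(path)
    with path.open("w") as fh:
        for lab, row in zip(rec.labels, rec.data):
            fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def write_truth_tsv(truth: SyntheticTruth, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_index": np.arange(truth.state_labels.size),
            "state_id": truth.state_labels,
        }
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["state_id"].to_numpy()


def sl_tensor_to_tsv(t: SLTensor, path: str | Path) -> None:
    """Long-format export: sample, k1, k2, value."""
    v, e = t.values.shape
    samples = np.repeat(np.arange(v), e)
    k1 = np.tile([p[0] for p in t.edge_index], v)
    k2 = np.tile([p[1] for p in t.edge_index], v)
    pd.DataFrame(
        {"sample": samples, "k1": k1, "k2": k2, "value": t.values.ravel()}
    ).to_csv(path, sep="\t", index=False)


def states_to_table(states: list[NetworkState], sample_period: float) -> pd.DataFrame:
    rows = [
        {
            "subject": s.subject,
            "epoch": s.epoch,
            "band": s.band,
            "cluster": s.cluster,
            "start_ms": s.start * sample_period,
            "end_ms": (s.end + 1) * sample_period,
            "duration_ms": s.duration_ms,
        }
        for s in states
    ]
    return pd.DataFrame(rows)


def save_similarity_heatmap(sim: np.ndarray, path: str | Path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(sim, cmap="inferno", vmin=0, vmax=1, origin="lower")
    ax.set_xlabel("sample")
    ax.set_ylabel("sample")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="cosine similarity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
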