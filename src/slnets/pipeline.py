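"""End-to-end orchestration: simulate/ingest -> preprocess -> SL ->
significance -> metrics -> similarity -> segmentation -> repertoire.

Each stage writes its outputs under a run directory and is skipped on rerun
if its outputs already exist (delete the run directory or pass
``force=True`` to recompute).  A manifest records the configuration, all
seeds, and package versions, so a run is reproducible from the manifest
alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .edge_stats import edge_pvalues, fdr_mask, surrogate_sl_ensemble
from .io import (
    read_recording,
    read_truth_tsv,
    save_similarity_heatmap,
    states_to_table,
    write_recording_tsv,
    write_truth_tsv,
)
from .metrics import metric_series
from .preprocess import (
    Epoch,
    bandpass_reference_standardize,
    epoch_and_downsample,
    get_band,
    reject_artifacts,
)
from .repertoire import (
    build_ensembles,
    consensus_families,
    detect_families,
    significant_similarity,
)
from .similarity import cosine_similarity_matrix, edge_communities
from .sl import SLTensor, compute_sl_tensor, derive_sl_params
from .states import (
    EvoConfig,
    Partition,
    absorb_short_runs,
    evolve,
    extract_states,
    refine_boundaries,
)
from .synthetic import CouplingSchedule, gen_switching_epoch

__all__ = ["PipelineConfig", "run_pipeline", "simulate_preset_config"]


@dataclass
class PipelineConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    band: str = "broadband"
    epoch_len_s: float = 5.0
    target_fs: float = 500.0
    amp_limit: float = 200.0
    slope_limit: float = 75.0
    z_limit: float = 3.0
    kurt_z_limit: float = 5.0
    reject: bool = True
    average_reference: bool = True
    n_rec: int = 10
    p_ref: float = 0.05
    # explicit SL parameter override (keys l, m, w1, w2, n_rec); empty dict
    # derives parameters from the band via derive_sl_params
    sl_params: dict = field(default_factory=dict)
    n_surr: int = 200
    q: float = 1e-4
    metrics_stride: int = 1
    n_null: int = 20
    n_restarts: int = 10
    evolution: dict = field(
        default_factory=lambda: {"pop_size": 30, "generations": 200}
    )
    # clustering features for segmentation: "similarity" clusters each
    # sample's cosine-similarity profile (strided by profile_stride),
    # "sl" clusters the raw SL vectors
    cluster_features: str = "similarity"
    profile_stride: int = 4
    # runs shorter than this many samples are folded into a neighbouring
    # state before extraction (flicker below the SL temporal resolution)
    min_state_samples: int = 5
    n_ensembles: int = 100
    n_perm: int = 1000
    alpha: float = 1e-6
    seed: int = 0
    # inputs: mapping subject -> list of recording files, or a simulate block
    inputs: dict = field(default_factory=dict)
    input_fs: float | None = None
    simulate: dict = field(default_factory=dict)

    def derive_params(self):
        from .sl import SLParams

        if self.sl_params:
            return SLParams(**self.sl_params)
        return derive_sl_params(
            get_band(self.band), self.target_fs, self.n_rec, self.p_ref
        )

    def validate(self) -> None:
        p = self.derive_params()
        if p.w1 >= p.w2:
            raise ValueError("derived SL window is empty (w1 >= w2)")
        if not self.inputs and not self.simulate:
            raise ValueError("config needs either inputs or a simulate block")
        EvoConfig(**{**self.evolution, "seed": 0})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate_preset_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale simulation preset: 4 subjects x 2 epochs, 9 channels,
    3 planted coupling topographies per epoch, 250 Hz, broadband.

    Sized so a full run (including a 60-surrogate significance stage and
    evolutionary segmentation of every epoch) completes on one CPU in a few
    minutes.
    """
    return PipelineConfig(
        band="broadband",
        epoch_len_s=5.0,
        target_fs=250.0,
        reject=False,
        average_reference=False,
        n_rec=10,
        p_ref=0.1,
        # short-span embedding: the stochastic band-limited sources have no
        # low-dimensional attractor to reconstruct, and a 10-sample span
        # localizes state switches far better than the band-derived m=24
        sl_params={"l": 2, "m": 6, "w1": 20, "w2": 119, "n_rec": 10},
        n_surr=60,
        metrics_stride=25,
        evolution={"pop_size": 30, "generations": 200},
        n_ensembles=50,
        seed=seed,
        simulate={
            "n_subjects": 4,
            "n_epochs": 2,
            "n_channels": 9,
            "coupling": 1.0,
            "noise_sd": 0.05,
            "n_states": 3,
        },
    )


#: parallel triple classes of the affine plane over GF(3) on 9 points;
#: lines from different classes share at most one point, so the triangles
#: they induce have pairwise disjoint edge sets.
_TRIPLE_CLASSES_9 = [
    [(0, 1, 2), (3, 4, 5), (6, 7, 8)],
    [(0, 3, 6), (1, 4, 7), (2, 5, 8)],
    [(0, 4, 8), (1, 5, 6), (2, 3, 7)],
    [(0, 5, 7), (1, 3, 8), (2, 4, 6)],
]


def _planted_topographies(n_channels: int, n_states: int, coupling: float):
    """Coupling matrices with disjoint strongly-coupled edge sets per state.

    With 9 channels (and up to 4 states) each state couples three
    driver/response/response triples, yielding nine strong edges per state
    whose sets are disjoint across states; each response receives a single
    driver, keeping total received drive <= 1.  Other channel counts fall
    back to disjoint strongly-coupled pairs.
    """
    mats = []
    if n_channels == 9 and n_states <= len(_TRIPLE_CLASSES_9):
        for s in range(n_states):
            c = np.zeros((9, 9))
            for d, r1, r2 in _TRIPLE_CLASSES_9[s]:
                c[d, r1] = c[r1, d] = coupling
                c[d, r2] = c[r2, d] = 0.9 * coupling
            mats.append(c)
        return mats
    all_edges = [
        (i, j) for i in range(n_channels) for j in range(i + 1, n_channels)
    ]
    used = set()
    for s in range(n_states):
        c = np.zeros((n_channels, n_channels))
        chosen = []
        busy: set[int] = set()
        for e in all_edges:
            if e in used or e[0] in busy or e[1] in busy:
                continue
            chosen.append(e)
            busy.update(e)
            if len(chosen) * 2 >= n_channels:
                break
        for i, j in chosen:
            c[i, j] = c[j, i] = coupling
            used.add((i, j))
        mats.append(c)
    return mats


def _simulate_stage(cfg: PipelineConfig, out: Path) -> dict[str, list[Path]]:
    sim = cfg.simulate
    band = get_band(cfg.band)
    n_samples = int(cfg.epoch_len_s * cfg.target_fs)
    topos = _planted_topographies(
        sim.get("n_channels", 8), sim.get("n_states", 3), sim.get("coupling", 0.85)
    )
    n_states = len(topos)
    rec_dir = out / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, list[Path]] = {}
    idx = 0
    for s in range(sim.get("n_subjects", 4)):
        subject = f"sub{s:02d}"
        inputs[subject] = []
        for e in range(sim.get("n_epochs", 2)):
            order = np.roll(np.arange(n_states), idx)
            durs = np.full(n_states, n_samples // n_states)
            durs[-1] += n_samples - durs.sum()
            schedule = CouplingSchedule(
                segments=[(int(d), topos[o]) for d, o in zip(durs, order)],
                n_channels=sim.get("n_channels", 8),
                seed=cfg.seed * 10007 + idx,
            )
            rec, truth = gen_switching_epoch(
                schedule, band, fs=cfg.target_fs, noise_sd=sim.get("noise_sd", 0.1)
            )
            truth.state_labels = order[truth.state_labels]  # planted topography id
            path = rec_dir / f"{subject}_ep{e}.tsv"
            write_recording_tsv(rec, path)
            write_truth_tsv(truth, rec_dir / f"{subject}_ep{e}_truth.tsv")
            inputs[subject].append(path)
            idx += 1
    return inputs


def _preprocess_stage(
    cfg: PipelineConfig, inputs: dict[str, list[Path]]
) -> dict[str, list[Epoch]]:
    band = get_band(cfg.band)
    fs_in = cfg.input_fs or cfg.target_fs
    epochs: dict[str, list[Epoch]] = {}
    for subject, paths in inputs.items():
        raw_epochs = []
        for p in paths:
            rec = read_recording(p, fs=fs_in)
            raw_epochs.extend(
                epoch_and_downsample(rec, cfg.epoch_len_s, cfg.target_fs)
            )
        if cfg.reject:
            raw_epochs, _ = reject_artifacts(
                raw_epochs,
                cfg.amp_limit,
                cfg.slope_limit,
                cfg.z_limit,
                cfg.kurt_z_limit,
            )
        done = []
        for i, ep in enumerate(raw_epochs):
            ep = bandpass_reference_standardize(
                ep, band, average_reference=cfg.average_reference
            )
            ep.source = subject
            ep.index = i
            done.append(ep)
        epochs[subject] = done
    return epochs


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path, force: bool = False) -> Path:
    """Execute every stage and return the run directory."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    band = get_band(cfg.band)
    params = cfg.derive_params()

    manifest = {
        "slnets_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "sl_params": {
            "l": params.l,
            "m": params.m,
            "w1": params.w1,
            "w2": params.w2,
            "n_rec": params.n_rec,
        },
    }

    # --- simulate / ingest -------------------------------------------------
    if cfg.simulate:
        marker = out / "recordings"
        if force or not marker.exists():
            inputs = _simulate_stage(cfg, out)
        else:
            inputs = {}
            for p in sorted(marker.glob("sub*_ep*.tsv")):
                if p.stem.endswith("_truth"):
                    continue
                subject = p.stem.split("_")[0]
                inputs.setdefault(subject, []).append(p)
    else:
        inputs = {s: [Path(p) for p in ps] for s, ps in cfg.inputs.items()}

    # --- preprocess --------------------------------------------------------
    epochs = _preprocess_stage(cfg, inputs)

    # --- SL + significance + metrics + similarity + states -----------------
    tensors: dict[tuple[str, int], SLTensor] = {}
    states_by_subject: dict[str, list] = {s: [] for s in epochs}
    seg_dir = out / "segmentation"
    seg_dir.mkdir(exist_ok=True)
    all_tables = []
    eidx = 0
    for subject, eps in epochs.items():
        for ep in eps:
            tag = f"{subject}_ep{ep.index}"
            masked_path = seg_dir / f"{tag}_masked"
            if not force and masked_path.with_suffix(".npz").exists():
                masked = SLTensor.load(masked_path)
            else:
                tensor = compute_sl_tensor(ep, params)
                ens = surrogate_sl_ensemble(
                    ep, params, n_surr=cfg.n_surr, seed=cfg.seed * 7919 + eidx
                )
                pvals = edge_pvalues(tensor, ens)
                mask = fdr_mask(pvals, q=cfg.q)
                masked = mask.apply(tensor)
                masked.save(masked_path)
            tensors[(subject, ep.index)] = masked

            # metrics (strided) and similarity artifacts
            met_path = seg_dir / f"{tag}_metrics.tsv"
            if force or not met_path.exists():
                sub = SLTensor(
                    values=masked.values[:: cfg.metrics_stride],
                    first_valid_index=masked.first_valid_index,
                    sample_period=masked.sample_period * cfg.metrics_stride,
                    edge_index=masked.edge_index,
                    params=masked.params,
                )
                metric_series(
                    sub, n_null=cfg.n_null, n_restarts=cfg.n_restarts, seed=cfg.seed
                ).to_csv(met_path, sep="\t", index=False)
            sim = cosine_similarity_matrix(masked)
            sim_path = seg_dir / f"{tag}_similarity.png"
            if force or not sim_path.exists():
                np.savez_compressed(
                    seg_dir / f"{tag}_similarity.npz", values=sim.values
                )
                save_similarity_heatmap(sim.values, sim_path, title=tag)
                comm = edge_communities(masked, seed=cfg.seed)
                pd.DataFrame(
                    {
                        "k1": [e[0] for e in comm.edge_index],
                        "k2": [e[1] for e in comm.edge_index],
                        "community": comm.labels,
                    }
                ).to_csv(seg_dir / f"{tag}_edge_communities.tsv", sep="\t", index=False)

            # segmentation
            if cfg.cluster_features == "similarity":
                features = sim.values[:, :: cfg.profile_stride]
            elif cfg.cluster_features == "sl":
                features = masked.values
            else:
                raise ValueError(
                    f"unknown cluster_features {cfg.cluster_features!r}"
                )
            part_path = seg_dir / f"{tag}_labels.tsv"
            if not force and part_path.exists():
                labels = pd.read_csv(part_path, sep="\t")["cluster"].to_numpy()
                part = Partition(labels)
            else:
                evo = EvoConfig(**{**cfg.evolution, "seed": cfg.seed * 104729 + eidx})
                part, _ = evolve(features, evo)
                part = absorb_short_runs(part, features, cfg.min_state_samples)
                part = refine_boundaries(part, features)
                pd.DataFrame(
                    {"sample": np.arange(part.n_samples), "cluster": part.labels}
                ).to_csv(part_path, sep="\t", index=False)
            sts = extract_states(
                part, masked, subject=subject, epoch=ep.index, band=cfg.band
            )
            states_by_subject[subject].extend(sts)
            tab = states_to_table(sts, masked.sample_period)
            all_tables.append(tab)
            eidx += 1

    states_table = pd.concat(all_tables, ignore_index=True)
    states_table.to_csv(out / "states.tsv", sep="\t", index=False)

    # --- repertoire --------------------------------------------------------
    ensembles = build_ensembles(
        states_by_subject, n_ensembles=cfg.n_ensembles, seed=cfg.seed
    )
    partitions = []
    for i, ens in enumerate(ensembles):
        binary = significant_similarity(
            ens, n_perm=cfg.n_perm, alpha=cfg.alpha, seed=cfg.seed * 2 + i
        )
        partitions.append(
            detect_families(binary, ens.representatives(), seed=cfg.seed)
        )
    consensus = consensus_families(partitions, seed=cfg.seed)

    summary = {
        "n_subjects": len(epochs),
        "n_epochs": int(sum(len(v) for v in epochs.values())),
        "n_states": int(states_table.shape[0]),
        "n_meta_families": int(consensus.n_meta),
        "state_fraction_per_meta_family": consensus.state_fraction.tolist(),
        "target_time_ms": float(ensembles[0].target_time),
    }

    # planted-truth evaluation when the run was simulated
    if cfg.simulate:
        purity = _consensus_purity(
            cfg, out, ensembles, partitions, consensus
        )
        summary["meta_family_purity"] = purity
    (out / "repertoire_summary.json").write_text(json.dumps(summary, indent=1))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


def _consensus_purity(cfg, out, ensembles, partitions, consensus) -> float:
    """Fraction of ensemble states whose consensus meta-family matches the
    majority planted topography of that meta-family."""
    rec_dir = out / "recordings"
    truths = {}
    for p in sorted(rec_dir.glob("sub*_truth.tsv")):
        subject, ep = p.stem.split("_")[0], int(p.stem.split("_")[1][2:])
        truths[(subject, ep)] = read_truth_tsv(p)
    band = get_band(cfg.band)
    params = cfg.derive_params()
    first_valid = params.w2 - 1

    state_meta = []
    state_true = []
    for eidx, (ens, partn) in enumerate(zip(ensembles, partitions)):
        # map local family -> meta id for this ensemble
        fam_meta = {}
        sel = consensus.family_ensemble == eidx
        for loc, meta in zip(
            consensus.family_local_id[sel], consensus.meta_of_family[sel]
        ):
            fam_meta[int(loc)] = int(meta)
        for s, fam in zip(ens.states, partn.labels):
            truth = truths.get((s.subject, s.epoch))
            if truth is None:
                continue
            span = truth[s.start + first_valid : s.end + first_valid + 1]
            true_lab = int(np.bincount(span).argmax())
            state_meta.append(fam_meta[int(fam)])
            state_true.append(true_lab)
    state_meta = np.array(state_meta)
    state_true = np.array(state_true)
    correct = 0
    for m in np.unique(state_meta):
        sel = state_meta == m
        maj = np.bincount(state_true[sel]).argmax()
        correct += int((state_true[sel] == maj).sum())
    return float(correct / state_meta.size)
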