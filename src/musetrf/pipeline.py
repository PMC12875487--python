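"""End-to-end orchestration: stimuli → information → TRF → ERP result tables.

``run_pipeline`` executes the complete analysis on either a directory of MIDI
stimuli or a synthetic fixture, against simulated multi-subject EEG, and
``write_outputs`` serializes every result table deterministically (stable row
order, fixed float formatting, no timestamps) so identical configurations
yield byte-identical outputs.
"""

from __future__ import annotations

import json
import platform
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import ConfigError
from .features import FeatureMatrix, build_feature_matrix
from .infodyn import InfoEstimates, estimate_information, estimates_to_frame
from .midi import Melody, derive_viewpoints, read_melody_table, read_midi, write_melody_table
from .preproc import DEFAULT_REFERENCE, EEGRecording, preprocess_recording
from .simulate import GenerativeSpec, SimulatedStudy, generate_eeg
from .stimgen import ShuffleSpec, generate_corpus, select_extremes, shuffle_melody
from .trf import AccuracyTable, LagWindow, build_super_subject, cross_validate_subjects
from .vp import ReducedSpec, delta_r, group_stats, roi_mean, select_roi, shuffle_features
from . import erp as erpmod

__all__ = ["PipelineResult", "run_pipeline", "write_outputs", "load_stimuli"]


def _sub_seed(seed: int, tag: str) -> int:
    """Deterministic child seed for a named pipeline stage."""
    return int(np.random.default_rng([seed, zlib.crc32(tag.encode())]).integers(2**31))


@dataclass
class PipelineResult:
    """Everything a run produced, in memory."""

    config: RunConfig
    melodies: dict[str, Melody]
    conditions: dict[str, str]
    info: dict[str, InfoEstimates]
    features: dict[str, FeatureMatrix]
    study: SimulatedStudy
    eeg_clean: dict[str, dict[str, np.ndarray]]
    accuracy: dict[str, AccuracyTable]
    roi: np.ndarray
    tidy: pd.DataFrame
    stats: dict
    erp_times: np.ndarray
    clusters: dict[str, list]
    erp_rejected_fraction: dict[str, float] = field(default_factory=dict)


def load_stimuli(directory: str | Path) -> list[Melody]:
    """Read every ``.mid``/``.midi``/``.tsv`` melody in a directory, sorted by name."""
    directory = Path(directory)
    if not directory.is_dir():
        raise ConfigError(f"stimulus directory {directory} does not exist")
    melodies = []
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in (".mid", ".midi"):
            melodies.append(read_midi(p, melody_id=p.stem))
        elif p.suffix.lower() == ".tsv":
            melodies.append(read_melody_table(p, melody_id=p.stem))
    if not melodies:
        raise ConfigError(f"no melody files found in {directory}")
    return melodies


def _assemble_corpus(cfg: RunConfig) -> tuple[dict[str, Melody], dict[str, str]]:
    """Real (loaded or generated) melodies plus their shuffled controls.

    Controls are built from the melodies with the highest and lowest mean
    timing surprise under a preliminary information pass on the real corpus.
    """
    if cfg.stimuli_dir is not None:
        real = load_stimuli(cfg.stimuli_dir)
    else:
        real = generate_corpus(
            cfg.n_real,
            n_notes=cfg.n_notes,
            pitch_order=cfg.pitch_order,
            rhythm_order=cfg.rhythm_order,
            temperature=cfg.temperature,
            seed=_sub_seed(cfg.seed, "stimgen"),
            sixteenth_duration=cfg.sixteenth_duration,
        )
    real = [Melody(id=m.id, notes=m.notes, condition="real",
                   sixteenth_duration=m.sixteenth_duration) for m in real]

    melodies = {m.id: m for m in real}
    conditions = {m.id: "real" for m in real}

    if cfg.n_shuffled > 0:
        if cfg.n_shuffled > len(real):
            raise ConfigError("n_shuffled exceeds the number of real melodies")
        folds = min(cfg.folds, len(real))
        pre_info = estimate_information(
            real, folds=folds, max_order=cfg.max_order, bias=cfg.bias,
            seed=_sub_seed(cfg.seed, "infodyn-pre"), ltm_online=cfg.ltm_online,
        )
        mean_st = {mid: float(np.nanmean(est.St)) for mid, est in pre_info.items()}
        chosen = select_extremes(mean_st, cfg.n_shuffled)
        for i, mid in enumerate(chosen):
            spec = ShuffleSpec(
                seed=_sub_seed(cfg.seed, f"shuffle-{mid}"),
                sixteenth_duration=melodies[mid].sixteenth_duration
                or cfg.sixteenth_duration,
            )
            shuf = shuffle_melody(melodies[mid], spec)
            melodies[shuf.id] = shuf
            conditions[shuf.id] = "shuffled"
    return melodies, conditions


def _preprocess_study(
    study: SimulatedStudy, features: Mapping[str, FeatureMatrix], cfg: RunConfig
) -> dict[str, dict[str, np.ndarray]]:
    """Concatenate each subject's melodies, run the cleaning pipeline, split back."""
    mels = sorted(features)
    lengths = [features[m].n_samples for m in mels]
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    segments = [(int(bounds[i]), int(bounds[i + 1])) for i in range(len(mels))]
    if all(name in study.layout_names for name in DEFAULT_REFERENCE):
        refs = DEFAULT_REFERENCE
    else:  # generic montage: common average reference
        refs = study.layout_names

    clean: dict[str, dict[str, np.ndarray]] = {}
    for subj in sorted(study.eeg):
        data = np.concatenate([study.eeg[subj][m] for m in mels], axis=1)
        rec = EEGRecording(
            data=data,
            fs=study.fs,
            channel_names=study.layout_names,
            positions=study.positions,
        )
        rec = preprocess_recording(
            rec,
            low=cfg.low_hz,
            high=cfg.high_hz,
            fs_out=study.fs,
            bad_z=cfg.bad_z,
            ref_labels=refs,
            radius_mm=cfg.interp_radius_mm,
            segments=segments,
        )
        clean[subj] = {
            m: rec.data[:, a:b] for m, (a, b) in zip(mels, segments)
        }
    return clean


def _erp_analysis(
    eeg_clean: Mapping[str, Mapping[str, np.ndarray]],
    melodies: Mapping[str, Melody],
    info: Mapping[str, InfoEstimates],
    conditions: Mapping[str, str],
    positions: np.ndarray,
    cfg: RunConfig,
) -> tuple[np.ndarray, dict[str, list], dict[str, float]]:
    """Surprise-quantile ERP contrasts with cluster permutation, per condition."""
    surprise = {
        "St": {mid: info[mid].St for mid in melodies},
        "Sp": {mid: info[mid].Sp for mid in melodies},
    }
    present_conditions = sorted(set(conditions.values()))
    adjacency = erpmod.channel_adjacency(positions, radius_mm=cfg.adjacency_radius_mm)

    subj_avgs: dict[tuple[str, str, str], list[np.ndarray]] = {}
    times = None
    rejected: dict[str, float] = {}
    for subj in sorted(eeg_clean):
        sets = [
            erpmod.epoch(eeg_clean[subj][mid], melodies[mid], fs=cfg.fs)
            for mid in sorted(melodies)
        ]
        epochs = erpmod.concatenate(sets)
        n_before = len(epochs)
        epochs = erpmod.reject_trials(epochs)
        rejected[subj] = 1.0 - len(epochs) / n_before
        for skey, smap in surprise.items():
            labelled = erpmod.quantile_split(epochs, smap, q=cfg.quantile).trim()
            if times is None:
                times = labelled.times
            for cond in present_conditions:
                for quant in ("highS", "lowS"):
                    try:
                        avg = erpmod.average_erp(labelled, quant, condition=cond)
                    except ConfigError:
                        continue
                    subj_avgs.setdefault((skey, cond, quant), []).append(avg)

    clusters: dict[str, list] = {}
    for skey in surprise:
        for cond in present_conditions:
            hi = subj_avgs.get((skey, cond, "highS"))
            lo = subj_avgs.get((skey, cond, "lowS"))
            if not hi or not lo or len(hi) != len(lo):
                continue
            clusters[f"{skey}:{cond}"] = erpmod.cluster_permutation(
                np.stack(hi),
                np.stack(lo),
                adjacency,
                n_perm=cfg.n_perm,
                alpha_cluster=cfg.cluster_alpha,
                min_channels=cfg.min_neighbors,
                seed=_sub_seed(cfg.seed, f"cluster-{skey}-{cond}"),
            )
    return times, clusters, rejected


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full analysis for one configuration; no files are written."""
    melodies, conditions = _assemble_corpus(cfg)
    mel_list = [melodies[mid] for mid in sorted(melodies)]

    folds = min(cfg.folds, len(mel_list))
    info = estimate_information(
        mel_list, folds=folds, max_order=cfg.max_order, bias=cfg.bias,
        seed=_sub_seed(cfg.seed, "infodyn"), ltm_online=cfg.ltm_online,
    )

    features = {}
    for mid in sorted(melodies):
        intervals = derive_viewpoints(melodies[mid])[2]
        features[mid] = build_feature_matrix(
            melodies[mid], info[mid], intervals,
            fs=cfg.fs,
            include_flux=cfg.include_flux,
            include_envelope=cfg.include_envelope,
            include_ioi_next=cfg.include_ioi_next,
            audio_sr=cfg.audio_sr,
            n_bands=cfg.n_bands,
        )

    window = LagWindow(cfg.lag_min_ms, cfg.lag_max_ms, cfg.fs)
    info_feats = tuple(
        f for f in ("St", "Et", "Sp", "Ep") if f in cfg.active_features
    )
    gen = GenerativeSpec(
        active_features=cfg.active_features,
        snr=cfg.snr,
        n_subjects=cfg.n_subjects,
        latency_jitter_ms=cfg.latency_jitter_ms,
        gain_sd=cfg.gain_sd,
        n_channels=cfg.n_channels,
        seed=_sub_seed(cfg.seed, "simulate"),
        window=window,
        condition_gains=(
            {"shuffled": {f: cfg.shuffled_info_gain for f in info_feats}}
            if info_feats
            else {}
        ),
    )
    study = generate_eeg(features, gen, conditions=conditions)
    eeg_clean = _preprocess_study(study, features, cfg)
    ground_truth = build_super_subject(eeg_clean)

    lambdas = 10.0 ** np.arange(cfg.lambda_min_exp, cfg.lambda_max_exp + 1, dtype=float)
    accuracy = {
        "full": cross_validate_subjects(
            features, eeg_clean, ground_truth, lambdas, window, model_tag="full"
        )
    }
    roi = select_roi(accuracy["full"], fraction=cfg.roi_fraction)

    tidy_parts = []
    for name in cfg.reduced_models:
        spec = ReducedSpec.standard(
            name,
            seed=_sub_seed(cfg.seed, f"reduce-{name}"),
            n_randomizations=cfg.n_randomizations,
        )
        tables = []
        for k in range(cfg.n_randomizations):
            red_feats = {
                mid: shuffle_features(features[mid], spec, randomization=k)
                for mid in sorted(features)
            }
            tables.append(
                cross_validate_subjects(
                    red_feats, eeg_clean, ground_truth, lambdas, window,
                    model_tag=name,
                )
            )
        accuracy[name] = tables[0]
        dr = delta_r(accuracy["full"], tables)
        tidy_parts.append(roi_mean(dr, roi, conditions))
    tidy = pd.concat(tidy_parts, ignore_index=True) if tidy_parts else pd.DataFrame(
        columns=["subject", "melody", "condition", "model", "dr"]
    )

    stats: dict = {}
    if len(tidy):
        stats["all_models"] = group_stats(tidy)
        if {"timing", "pitch"} <= set(cfg.reduced_models):
            stats["timing_vs_pitch"] = group_stats(
                tidy[tidy["model"].isin(["timing", "pitch"])].reset_index(drop=True)
            )
        if {"ioi", "ipi"} <= set(cfg.reduced_models):
            stats["ioi_vs_ipi"] = group_stats(
                tidy[tidy["model"].isin(["ioi", "ipi"])].reset_index(drop=True)
            )

    times, clusters, rejected = _erp_analysis(
        eeg_clean, melodies, info, conditions, study.positions, cfg
    )

    return PipelineResult(
        config=cfg,
        melodies=melodies,
        conditions=conditions,
        info=info,
        features=features,
        study=study,
        eeg_clean=eeg_clean,
        accuracy=accuracy,
        roi=roi,
        tidy=tidy,
        stats=stats,
        erp_times=times,
        clusters=clusters,
        erp_rejected_fraction=rejected,
    )


# --------------------------------------------------------------------------
# deterministic serialization
# --------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def _accuracy_frame(accuracy: Mapping[str, AccuracyTable]) -> pd.DataFrame:
    rows = []
    for model in sorted(accuracy):
        t = accuracy[model]
        for si, subj in enumerate(t.subjects):
            for mi, mel in enumerate(t.melodies):
                rows.append(
                    (model, subj, mel, float(t.r[si, mi].mean()), float(t.lambdas[si]))
                )
    return pd.DataFrame(
        rows, columns=["model", "subject", "melody", "mean_r", "lambda"]
    )


def _cluster_frame(clusters: Mapping[str, list], times: np.ndarray) -> pd.DataFrame:
    rows = []
    for contrast in sorted(clusters):
        for rank, c in enumerate(clusters[contrast]):
            rows.append(
                (
                    contrast,
                    rank,
                    int(c.polarity),
                    float(c.mass),
                    float(c.p),
                    float(times[c.time_indices.min()]),
                    float(times[c.time_indices.max()]),
                    int(len(np.unique(c.channels))),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "contrast", "rank", "polarity", "mass", "p", "t_min_s", "t_max_s",
            "n_channels",
        ],
    )


def write_outputs(result: PipelineResult, out_dir: str | Path | None = None) -> Path:
    """Write all result tables (and optionally figures) under ``out_dir``.

    Everything is serialized with stable ordering and fixed float formatting;
    no timestamps or absolute paths are embedded, so repeated runs of the same
    configuration produce byte-identical files.
    """
    cfg = result.config
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    mel_dir = out / "melodies"
    mel_dir.mkdir(exist_ok=True)
    for mid in sorted(result.melodies):
        write_melody_table(result.melodies[mid], mel_dir / f"{mid}.tsv")

    estimates_to_frame(result.info).to_csv(
        out / "info_estimates.csv", index=False, float_format=_FLOAT_FMT
    )
    _accuracy_frame(result.accuracy).to_csv(
        out / "accuracy.csv", index=False, float_format=_FLOAT_FMT
    )
    result.tidy.sort_values(["model", "condition", "subject", "melody"]).to_csv(
        out / "delta_r_roi.csv", index=False, float_format=_FLOAT_FMT
    )
    (out / "group_stats.json").write_text(
        json.dumps(result.stats, indent=2, sort_keys=True) + "\n"
    )
    _cluster_frame(result.clusters, result.erp_times).to_csv(
        out / "erp_clusters.csv", index=False, float_format=_FLOAT_FMT
    )
    provenance = {
        "package_version": __version__,
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "python": platform.python_version(),
        "n_melodies": len(result.melodies),
        "n_subjects": cfg.n_subjects,
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n"
    )
    if cfg.figures:
        _write_figures(result, out / "figures")
    return out


def _write_figures(result: PipelineResult, fig_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir.mkdir(parents=True, exist_ok=True)

    # Δr by condition and model
    if len(result.tidy):
        fig, ax = plt.subplots(figsize=(7, 4))
        cells = sorted(
            result.tidy.groupby(["model", "condition"], observed=True).groups
        )
        for x, (model, cond) in enumerate(cells):
            vals = result.tidy.query(
                "model == @model and condition == @cond"
            ).groupby("subject", observed=True)["dr"].mean()
            ax.scatter(np.full(len(vals), x), vals, s=12, alpha=0.6)
            ax.scatter([x], [vals.mean()], s=80, marker="_", color="k")
        ax.axhline(0, color="grey", lw=0.8)
        ax.set_xticks(range(len(cells)))
        ax.set_xticklabels([f"{m}\n{c}" for m, c in cells], fontsize=8)
        ax.set_ylabel("Δr (ROI mean)")
        fig.tight_layout()
        fig.savefig(fig_dir / "delta_r.svg", metadata={"Date": None})
        plt.close(fig)

    # grand-average ERP contrast traces per cluster contrast
    for contrast, clist in sorted(result.clusters.items()):
        if not clist:
            continue
        fig, ax = plt.subplots(figsize=(6, 3.5))
        best = clist[0]
        ax.plot(result.erp_times, np.zeros_like(result.erp_times), color="grey", lw=0.8)
        span = (
            result.erp_times[best.time_indices.min()],
            result.erp_times[best.time_indices.max()],
        )
        ax.axvspan(*span, alpha=0.2)
        ax.set_title(f"{contrast}: best cluster p={best.p:.3f}")
        ax.set_xlabel("time (s)")
        fig.tight_layout()
        fig.savefig(
            fig_dir / f"erp_{contrast.replace(':', '_')}.svg", metadata={"Date": None}
        )
        plt.close(fig)
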