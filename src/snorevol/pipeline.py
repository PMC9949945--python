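"""End-to-end orchestration: preprocess -> MFCC/AHC -> snore typing -> rules
-> (optional) SpO2 evaluation."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from snorevol import clustering, evaluation, formants, mfcc, rules
from snorevol.config import PipelineConfig
from snorevol.io import (
    AudioRecording,
    SpO2Trace,
    write_results_csv,
)
from snorevol.preprocess import Clip, preprocess

log = logging.getLogger("snorevol")


@dataclass
class PipelineResult:
    rows: list[dict]
    report: evaluation.EvaluationReport | None
    clips: list[Clip] = field(repr=False, default_factory=list)

    def summary(self) -> dict:
        if self.report is not None:
            return self.report.summary()
        return {"accuracy": None, "total": len(self.rows), "uncertain": None, "correct": None}


def run_pipeline(
    rec: AudioRecording,
    spo2: SpO2Trace | None = None,
    config: PipelineConfig | None = None,
    label_map: dict[int, str] | None = None,
) -> PipelineResult:
    """Run the full analysis on one recording.

    ``label_map`` optionally overrides the automatic RMS-based semantic
    assignment with an explicit ``{cluster_id: label}`` mapping.
    """
    cfg = (config or PipelineConfig()).validate()

    log.info("preprocess: band=[%g, %g] Hz, target=%g Hz, clip=%g s",
             cfg.band_low_hz, cfg.band_high_hz, cfg.target_rate_hz, cfg.clip_len_s)
    clips = preprocess(
        rec,
        band_low_hz=cfg.band_low_hz,
        band_high_hz=cfg.band_high_hz,
        target_rate_hz=cfg.target_rate_hz,
        clip_len_s=cfg.clip_len_s,
        butter_order=cfg.butter_order,
    )
    if not clips:
        warnings.warn("recording shorter than one clip; nothing to analyze")
        return PipelineResult(rows=[], report=None, clips=[])
    if len(clips) < cfg.n_clusters:
        raise ValueError(
            f"need at least {cfg.n_clusters} clips to cluster, got {len(clips)}"
        )

    log.info("features: MFCC %d coeffs, %d mels on %d clips",
             cfg.n_mfcc, cfg.n_mels, len(clips))
    feats = [
        mfcc.clip_feature(
            mfcc.mfcc(
                c,
                n_mfcc=cfg.n_mfcc,
                win_s=cfg.stft_win_ms / 1000.0,
                hop_s=cfg.stft_hop_ms / 1000.0,
                n_filters=cfg.n_mels,
                f_lo=cfg.fmin_hz,
                f_hi=cfg.fmax_hz,
            )
        )
        for c in clips
    ]
    dmat = mfcc.distance_matrix(feats)

    log.info("clustering: %s linkage, k=%d", cfg.linkage, cfg.n_clusters)
    tree = clustering.ahc_linkage(dmat, linkage=cfg.linkage)
    ids = clustering.cut_tree(tree, cfg.n_clusters)
    if label_map is not None:
        assignment = clustering.ClusterAssignment(cluster_id=ids, semantic=dict(label_map))
    else:
        assignment = clustering.assign_semantics(ids, clips)
    semantics = assignment.labels()

    snore_idx = [i for i, s in enumerate(semantics) if s == "snoring"]
    log.info("snore typing: %d snoring clips", len(snore_idx))
    snore_feats = []
    for i in snore_idx:
        episodes = formants.detect_snore_episodes(
            clips[i],
            episode_min_ms=cfg.episode_min_ms,
            order=cfg.lpc_order,
            win_ms=cfg.lpc_win_ms,
            overlap=cfg.lpc_overlap,
            bw_max_hz=cfg.formant_bw_max_hz,
            f_min_hz=cfg.formant_min_hz,
            f_max_hz=cfg.formant_max_hz,
        )
        snore_feats.append(formants.snore_features(episodes))
    snore_types = formants.classify_snore_type(snore_feats, seed=cfg.kmeans_seed)
    type_by_clip = dict(zip(snore_idx, snore_types))

    # elapsed time inside runs of simple snoring (chronological clip order)
    seq = [
        "simple" if type_by_clip.get(i) == "simple" else semantics[i]
        for i in range(len(clips))
    ]
    elapsed = rules.simple_snoring_elapsed(seq)

    rows = []
    pred_levels = []
    for i, clip in enumerate(clips):
        sem = semantics[i]
        stype = type_by_clip.get(i)
        mbpi_s = None
        elapsed_min = None
        if stype == "apneic":
            events = rules.detect_breath_events(clip, event_min_ms=cfg.event_min_ms)
            mbpi_s = rules.mbpi(events, cfg.clip_len_s)
        elif stype == "simple":
            elapsed_min = elapsed[i]
        level = rules.tidal_level(
            sem,
            snore_type=stype,
            mbpi_s=mbpi_s,
            elapsed_min=elapsed_min,
            mbpi_threshold_s=cfg.mbpi_threshold_s,
            ss_elapsed_threshold_min=cfg.ss_elapsed_threshold_min,
        )
        pred_levels.append(level)
        rows.append(
            {
                "clip_index": i,
                "label": stype if stype is not None else sem,
                "mbpi_s": mbpi_s,
                "elapsed_min": elapsed_min,
                "pred_level": level,
                "loo2": None,
                "ref_level": None,
            }
        )

    report = None
    if spo2 is not None:
        windows = [(c.start_s, c.end_s) for c in clips]
        report = evaluation.evaluate(pred_levels, spo2, windows)
        for row, v, ref in zip(rows, report.loo2_values, report.ref_levels):
            row["loo2"] = v
            row["ref_level"] = ref
        log.info("evaluation: accuracy=%s (%d/%d, %d uncertain)",
                 report.accuracy, report.correct,
                 report.total - report.uncertain, report.uncertain)
    return PipelineResult(rows=rows, report=report, clips=clips)


def write_outputs(result: PipelineResult, out_dir: str | Path, plot: bool = True) -> None:
    """Write results.csv, summary.json and (optionally) the 4-panel plot."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_results_csv(out_dir / "results.csv", result.rows)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2)
    if plot and result.rows:
        plot_summary(result, out_dir / "summary.png")


_LABEL_ORDER = {"apneic": 0, "simple": 1, "normal": 2, "uncertain": 3}
_LEVEL_ORDER = {"low": 0, "medium": 1, "high": 2, "uncertain": 3}


def plot_summary(result: PipelineResult, path: str | Path, spo2: SpO2Trace | None = None) -> None:
    """Four stacked panels: clip labels, predicted level, reference level,
    raw SpO2 (when available)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    idx = [r["clip_index"] for r in result.rows]
    fig, axes = plt.subplots(4, 1, figsize=(10, 8), sharex=True)
    axes[0].step(idx, [_LABEL_ORDER[r["label"]] for r in result.rows], where="mid")
    axes[0].set_yticks(range(4), ["apneic", "simple", "normal", "uncertain"])
    axes[0].set_ylabel("cluster")
    axes[1].step(idx, [_LEVEL_ORDER[r["pred_level"]] for r in result.rows], where="mid")
    axes[1].set_yticks(range(4), ["low", "medium", "high", "uncertain"])
    axes[1].set_ylabel("predicted")
    if result.report is not None:
        axes[2].step(idx, [_LEVEL_ORDER[l] for l in result.report.ref_levels], where="mid")
        axes[2].set_yticks(range(4), ["low", "medium", "high", "uncertain"])
        axes[3].plot(
            np.array(idx), [r["loo2"] for r in result.rows], marker=".", ls="-"
        )
        axes[3].set_ylabel("LoO2 (%)")
    axes[2].set_ylabel("reference")
    axes[3].set_xlabel("clip index (minutes)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
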