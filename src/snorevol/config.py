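"""Pipeline configuration with defaults matching the published parameters."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # preprocessing
    band_low_hz: float = 50.0
    band_high_hz: float = 2450.0
    target_rate_hz: float = 5000.0
    clip_len_s: float = 60.0
    butter_order: int = 4
    # MFCC
    n_mels: int = 40
    n_mfcc: int = 13
    stft_win_ms: float = 1000.0
    stft_hop_ms: float = 500.0
    fmin_hz: float = 50.0
    fmax_hz: float = 2450.0
    # clustering
    linkage: str = "average"
    n_clusters: int = 3
    # formants / snore typing
    lpc_order: int = 14
    lpc_win_ms: float = 20.0
    lpc_overlap: float = 0.5
    episode_min_ms: float = 300.0
    formant_bw_max_hz: float = 400.0
    formant_min_hz: float = 90.0
    formant_max_hz: float = 2400.0
    kmeans_seed: int = 0
    # rules
    mbpi_threshold_s: float = 10.0
    ss_elapsed_threshold_min: float = 4.0
    event_min_ms: float = 200.0

    def validate(self) -> "PipelineConfig":
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("require 0 < band_low_hz < band_high_hz")
        if self.band_high_hz >= self.target_rate_hz / 2:
            raise ValueError("band_high_hz must be below the target Nyquist")
        if self.n_mfcc > self.n_mels:
            raise ValueError("n_mfcc cannot exceed n_mels")
        if self.linkage not in {"average", "single", "complete", "ward"}:
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.lpc_order < 1:
            raise ValueError("lpc_order must be >= 1")
        if not 0 <= self.lpc_overlap < 1:
            raise ValueError("lpc_overlap must be in [0, 1)")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
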