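"""Bandpass filtering, downsampling and fixed-length segmentation.

Noise outside the 50-2500 Hz band that carries respiratory-sound energy is
removed with a zero-phase Butterworth filter applied at the original rate,
the signal is resampled to 5000 Hz, and the recording is tiled into
non-overlapping 60 s clips (trailing remainder discarded).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from snorevol.io import AudioRecording


@dataclass
class Clip:
    """One fixed-length segment of the processed recording.

    Boundaries are half-open ``[start_s, end_s)``; ``index`` is the 0-based
    position of the clip in the recording.
    """

    index: int
    samples: np.ndarray
    rate: float
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


def bandpass(
    rec: AudioRecording,
    low_hz: float,
    high_hz: float,
    order: int = 4,
) -> AudioRecording:
    """Zero-phase Butterworth bandpass.

    Applied forward-backward (``sosfiltfilt``) so event timing used by the
    pause analysis is not shifted by filter group delay.
    """
    nyq = rec.rate / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError("require 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(
            f"high_hz={high_hz} must be below Nyquist {nyq} of the recording"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return AudioRecording(samples=filtered, rate=rec.rate, t0=rec.t0)


def downsample(rec: AudioRecording, target_hz: float) -> AudioRecording:
    """Polyphase resampling to ``target_hz`` (must be below the source rate)."""
    if target_hz >= rec.rate:
        raise ValueError("target rate must be below the source rate")
    frac = Fraction(target_hz / rec.rate).limit_denominator(10000)
    out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator)
    return AudioRecording(samples=out, rate=target_hz, t0=rec.t0)


def segment(rec: AudioRecording, clip_len_s: float = 60.0) -> list[Clip]:
    """Tile the recording into non-overlapping clips of ``clip_len_s``.

    The trailing partial clip is discarded; a recording shorter than one
    clip yields an empty list.
    """
    if clip_len_s <= 0:
        raise ValueError("clip_len_s must be positive")
    samples_per_clip = int(round(clip_len_s * rec.rate))
    n_clips = len(rec.samples) // samples_per_clip
    clips = []
    for i in range(n_clips):
        lo = i * samples_per_clip
        clips.append(
            Clip(
                index=i,
                samples=rec.samples[lo : lo + samples_per_clip],
                rate=rec.rate,
                start_s=i * clip_len_s,
                end_s=(i + 1) * clip_len_s,
            )
        )
    return clips


def preprocess(
    rec: AudioRecording,
    band_low_hz: float = 50.0,
    band_high_hz: float = 2450.0,
    target_rate_hz: float = 5000.0,
    clip_len_s: float = 60.0,
    butter_order: int = 4,
) -> list[Clip]:
    """Full preprocessing chain: filter at the source rate, resample, segment."""
    rec = bandpass(rec, band_low_hz, band_high_hz, order=butter_order)
    if rec.rate > target_rate_hz:
        rec = downsample(rec, target_rate_hz)
    elif rec.rate < target_rate_hz:
        raise ValueError(
            f"recording rate {rec.rate} is below the target {target_rate_hz}"
        )
    return segment(rec, clip_len_s)
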