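"""Mel-spectrum / MFCC features per clip and the pairwise distance matrix.

Each clip is framed with 1000 ms windows at a 500 ms hop, projected onto a
40-filter Mel bank, log-compressed, and DCT-transformed.  The per-clip
feature is the frame-average of the MFCC matrix rows; clips are compared by
Euclidean distance between these vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import dct, rfft
from scipy.spatial.distance import pdist, squareform

from snorevol.preprocess import Clip

LOG_FLOOR = 1e-10


@dataclass
class MFCCMatrix:
    """Cepstral coefficients, one column per analysis frame."""

    coeffs: np.ndarray  # (n_mfcc, n_frames)
    frame_times: np.ndarray  # seconds, frame centers


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    """Map frequency in Hz to the Mel scale: 2595*log10(f/700 + 1)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")
    out = 2595.0 * np.log10(f / 700.0 + 1.0)
    return float(out) if out.ndim == 0 else out


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    f = np.asarray(m, dtype=np.float64)
    out = 700.0 * (10.0 ** (f / 2595.0) - 1.0)
    return float(out) if out.ndim == 0 else out


def mel_filterbank(
    n_filters: int,
    n_fft: int,
    rate: float,
    f_lo: float,
    f_hi: float,
) -> np.ndarray:
    """Triangular Mel filterbank, peak-normalized to 1.

    Filter centers are equally spaced on the Mel axis between
    ``hz_to_mel(f_lo)`` and ``hz_to_mel(f_hi)``.  Returns an array of shape
    ``(n_filters, n_fft//2 + 1)``.
    """
    if n_filters < 2:
        raise ValueError("need at least 2 filters")
    if not 0 <= f_lo < f_hi <= rate / 2:
        raise ValueError("require 0 <= f_lo < f_hi <= rate/2")
    mel_pts = np.linspace(hz_to_mel(f_lo), hz_to_mel(f_hi), n_filters + 2)
    hz_pts = mel_to_hz(mel_pts)
    freqs = np.arange(n_fft // 2 + 1) * rate / n_fft
    fb = np.zeros((n_filters, len(freqs)))
    for k in range(n_filters):
        left, center, right = hz_pts[k], hz_pts[k + 1], hz_pts[k + 2]
        rising = (freqs - left) / (center - left)
        falling = (right - freqs) / (right - center)
        fb[k] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def filter_centers_hz(n_filters: int, f_lo: float, f_hi: float) -> np.ndarray:
    mel_pts = np.linspace(hz_to_mel(f_lo), hz_to_mel(f_hi), n_filters + 2)
    return mel_to_hz(mel_pts[1:-1])


def _frame_count(n_samples: int, win: int, hop: int) -> int:
    if n_samples < win:
        return 0
    return (n_samples - win) // hop + 1


def mel_spectrogram(
    clip: Clip,
    win_s: float = 1.0,
    hop_s: float = 0.5,
    n_filters: int = 40,
    f_lo: float = 50.0,
    f_hi: float = 2450.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-Mel spectrogram of one clip.

    Returns ``(logmel, frame_times)`` with ``logmel`` of shape
    ``(n_filters, n_frames)`` where ``n_frames = floor((len - win)/hop)+1``.
    """
    if clip.samples.size == 0:
        raise ValueError("empty clip")
    win = int(round(win_s * clip.rate))
    hop = int(round(hop_s * clip.rate))
    n_frames = _frame_count(len(clip.samples), win, hop)
    if n_frames == 0:
        raise ValueError("clip shorter than one analysis window")
    n_fft = 1 << (win - 1).bit_length()  # next power of two >= win
    window = signal.get_window("hann", win, fftbins=True)
    fb = mel_filterbank(n_filters, n_fft, clip.rate, f_lo, f_hi)

    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = clip.samples[idx] * window[None, :]
    spec = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2  # (n_frames, bins)
    melpow = spec @ fb.T  # (n_frames, n_filters)
    logmel = np.log(np.maximum(melpow, LOG_FLOOR)).T
    frame_times = (np.arange(n_frames) * hop + win / 2) / clip.rate
    return logmel, frame_times


def mfcc(
    clip: Clip,
    n_mfcc: int = 13,
    win_s: float = 1.0,
    hop_s: float = 0.5,
    n_filters: int = 40,
    f_lo: float = 50.0,
    f_hi: float = 2450.0,
) -> MFCCMatrix:
    """MFCC matrix: orthonormal DCT-II of the log-Mel spectrum per frame."""
    logmel, frame_times = mel_spectrogram(clip, win_s, hop_s, n_filters, f_lo, f_hi)
    coeffs = dct(logmel, type=2, axis=0, norm="ortho")[:n_mfcc]
    return MFCCMatrix(coeffs=coeffs, frame_times=frame_times)


def clip_feature(m: MFCCMatrix) -> np.ndarray:
    """Average each coefficient row across frames -> one vector per clip."""
    if m.coeffs.size == 0 or m.coeffs.shape[1] < 1:
        raise ValueError("empty MFCC matrix")
    return m.coeffs.mean(axis=1)


def euclidean_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Straight-line distance between two feature vectors."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("feature vectors must have equal length")
    return float(np.sqrt(np.sum((p - q) ** 2)))


def distance_matrix(features: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise Euclidean distances, zero diagonal."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two feature vectors")
    return squareform(pdist(X, metric="euclidean"))
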