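"""Reading and writing the formats the pipeline exchanges.

Audio travels as RIFF WAV (PCM16 or float32), the oxygen-saturation trace
as a two-column CSV (``time_s,spo2_percent``) sampled at 1 Hz, and results
as a flat CSV table with one row per clip.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

RESULTS_COLUMNS = [
    "clip_index",
    "label",
    "mbpi_s",
    "elapsed_min",
    "pred_level",
    "loo2",
    "ref_level",
]


@dataclass
class AudioRecording:
    """Single-channel audio signal.

    Parameters
    ----------
    samples : ndarray of float
        Dimensionless amplitude, nominally in [-1, 1].
    rate : float
        Sampling rate in Hz, strictly positive.
    t0 : float
        Time offset of the first sample, seconds.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.samples.ndim != 1:
            raise ValueError("AudioRecording holds a single channel")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class SpO2Trace:
    """1 Hz oxygen-saturation series in percent."""

    values: np.ndarray
    rate: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.rate != 1.0:
            raise ValueError("SpO2Trace is defined at 1 Hz")
        if self.values.size and (
            self.values.min() < 0.0 or self.values.max() > 100.0
        ):
            raise ValueError("SpO2 values must lie in [0, 100]")


def read_wav(path: str | Path) -> AudioRecording:
    """Read a WAV file into a mono :class:`AudioRecording`.

    Multichannel files collapse to channel 0.  Integer PCM is rescaled to
    [-1, 1]; float content is passed through.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(max(abs(np.iinfo(data.dtype).min), np.iinfo(data.dtype).max))
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return AudioRecording(samples=samples, rate=float(rate))


def write_wav(path: str | Path, rec: AudioRecording) -> None:
    """Write a recording as float32 WAV."""
    wavfile.write(Path(path), int(rec.rate), rec.samples.astype(np.float32))


def read_spo2_csv(path: str | Path) -> SpO2Trace:
    """Read a 1 Hz SpO2 trace from a ``time_s,spo2_percent`` CSV.

    Raises
    ------
    ValueError
        If timestamps are not consecutive integer seconds or a value lies
        outside [0, 100].
    """
    df = pd.read_csv(path)
    missing = {"time_s", "spo2_percent"} - set(df.columns)
    if missing:
        raise ValueError(f"SpO2 CSV missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=np.float64)
    if len(t) == 0:
        raise ValueError("SpO2 CSV is empty")
    if not np.allclose(t, np.round(t)):
        raise ValueError("SpO2 timestamps must be integer seconds")
    if not np.array_equal(np.diff(t), np.ones(len(t) - 1)):
        raise ValueError("SpO2 timestamps must be consecutive seconds")
    values = df["spo2_percent"].to_numpy(dtype=np.float64)
    if values.min() < 0.0 or values.max() > 100.0:
        raise ValueError("SpO2 values must lie in [0, 100]")
    return SpO2Trace(values=values, t0=float(t[0]))


def write_spo2_csv(path: str | Path, trace: SpO2Trace) -> None:
    t = np.arange(len(trace.values)) + int(trace.t0)
    pd.DataFrame({"time_s": t, "spo2_percent": trace.values}).to_csv(
        path, index=False
    )


def write_results_csv(path: str | Path, rows: list[dict]) -> None:
    """Write the per-clip results table with the canonical column order."""
    df = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    df.to_csv(path, index=False)


def read_results_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
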