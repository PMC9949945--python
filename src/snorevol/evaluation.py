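"""Reference levels from the SpO2 trace and the accuracy score.

The per-clip reference is the lowest 1 Hz SpO2 sample in the clip window
(LoO2), banded into high (> 95 %), medium (90-95 % inclusive) and low
(< 90 %).  Accuracy is correct / (total - uncertain): clips the clustering
could not assess are removed from the denominator, never counted correct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from snorevol.io import SpO2Trace


@dataclass
class EvaluationReport:
    pred_levels: list[str]
    ref_levels: list[str]
    loo2_values: list[float]
    accuracy: float | None
    total: int
    uncertain: int
    correct: int

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "total": self.total,
            "uncertain": self.uncertain,
            "correct": self.correct,
        }


def loo2(trace: SpO2Trace, start_s: float, end_s: float) -> float:
    """Minimum SpO2 sample with timestamp in [start_s, end_s)."""
    if end_s <= start_s:
        raise ValueError("empty window")
    t = trace.t0 + np.arange(len(trace.values))
    mask = (t >= start_s) & (t < end_s)
    if not mask.any():
        raise ValueError(
            f"window [{start_s}, {end_s}) outside trace coverage"
        )
    return float(trace.values[mask].min())


def loo2_level(value: float) -> str:
    """Band a saturation percentage: >95 high, 90-95 medium, <90 low."""
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"SpO2 value out of range: {value}")
    if value > 95.0:
        return "high"
    if value >= 90.0:
        return "medium"
    return "low"


def accuracy(preds: list[str], refs: list[str]) -> tuple[float | None, int, int]:
    """Score = correct / (total - uncertain).

    Returns ``(accuracy, correct, uncertain)``; accuracy is ``None`` (with
    a warning) when every prediction is uncertain.
    """
    if len(preds) != len(refs):
        raise ValueError("prediction/reference length mismatch")
    uncertain = sum(1 for p in preds if p == "uncertain")
    denom = len(preds) - uncertain
    correct = sum(
        1 for p, r in zip(preds, refs) if p != "uncertain" and p == r
    )
    if denom == 0:
        warnings.warn("all clips uncertain; accuracy undefined")
        return None, correct, uncertain
    return correct / denom, correct, uncertain


def evaluate(
    pred_levels: list[str],
    trace: SpO2Trace,
    clip_windows: list[tuple[float, float]],
) -> EvaluationReport:
    """Build the per-clip report for aligned predictions and clip windows."""
    if len(pred_levels) != len(clip_windows):
        raise ValueError("one window per prediction required")
    loo2_values = [loo2(trace, s, e) for s, e in clip_windows]
    ref_levels = [loo2_level(v) for v in loo2_values]
    acc, correct, uncertain = accuracy(pred_levels, ref_levels)
    return EvaluationReport(
        pred_levels=list(pred_levels),
        ref_levels=ref_levels,
        loo2_values=loo2_values,
        accuracy=acc,
        total=len(pred_levels),
        uncertain=uncertain,
        correct=correct,
    )
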