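"""Labeled synthetic tracheal-sound minutes and consistent SpO2 traces.

Snores are synthesized with a source-filter model: a glottal-like impulse
train is shaped by a two-pole resonator whose center frequency plays the
role of F1.  Normal breathing is band-limited noise gated by an
inspiration/expiration envelope; uncertain minutes are near-silent noise.
The SpO2 generator dips each minute into the saturation band that the rule
table predicts for that minute's ground truth, so a perfect classifier
scores accuracy 1.0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.signal.windows import tukey

from snorevol.io import AudioRecording, SpO2Trace

MINUTE_S = 60.0
BURST_DUR_S = 1.2

# per-minute RMS targets; ordering (snore > normal > uncertain) drives the
# RMS-based semantic assignment downstream
SNORE_BURST_RMS = 0.30
NORMAL_BURST_RMS = 0.12
BACKGROUND_NOISE_AMP = 2e-3  # ambient/body noise floor of a real recording
UNCERTAIN_NOISE_AMP = 5e-4

SPO2_BASELINE = 97.0
SPO2_AS_SHORT_PAUSE = 92.0  # pause <= 10 s -> medium band
SPO2_AS_LONG_PAUSE = 88.0  # pause > 10 s -> low band
SPO2_SS_LATE = 93.0  # simple snoring from run minute 4 on


@dataclass
class ScenarioPlan:
    """Per-minute ground truth for a synthetic recording.

    ``labels`` holds one of ``normal`` / ``simple`` / ``apneic`` /
    ``uncertain`` per minute; ``pause_s`` gives the inserted breathing
    pause for each apneic minute (parallel list, ignored elsewhere, None
    allowed for non-apneic minutes).
    """

    labels: list[str]
    pause_s: list[float | None] = field(default_factory=list)
    seed: int = 0
    rate: float = 5000.0

    def __post_init__(self) -> None:
        valid = {"normal", "simple", "apneic", "uncertain"}
        bad = set(self.labels) - valid
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if not self.pause_s:
            self.pause_s = [12.0 if lab == "apneic" else None for lab in self.labels]
        if len(self.pause_s) != len(self.labels):
            raise ValueError("pause_s must parallel labels")
        for lab, p in zip(self.labels, self.pause_s):
            if lab == "apneic":
                if p is None or not 0 < p < MINUTE_S:
                    raise ValueError("apneic minutes need a pause in (0, 60) s")

    @property
    def n_minutes(self) -> int:
        return len(self.labels)


def _resonator_sos(f_hz: float, rate: float, bw_hz: float = 150.0) -> np.ndarray:
    """Two-pole resonator (one conjugate pair) at f_hz with given bandwidth."""
    r = np.exp(-np.pi * bw_hz / rate)
    theta = 2 * np.pi * f_hz / rate
    return np.array([[1.0, 0.0, 0.0, 1.0, -2 * r * np.cos(theta), r * r]])


def _snore_burst(
    rng: np.random.Generator,
    rate: float,
    f1_hz: float,
    dur_s: float = BURST_DUR_S,
    f0_hz: float = 100.0,
) -> np.ndarray:
    """One snore: impulse train at f0 plus weak noise through the resonator."""
    n = int(round(dur_s * rate))
    src = np.zeros(n)
    period = max(1, int(round(rate / f0_hz)))
    src[::period] = 1.0
    src += 0.1 * rng.standard_normal(n)
    out = signal.sosfilt(_resonator_sos(f1_hz, rate), src)
    out *= tukey(n, alpha=0.25)
    rms = np.sqrt(np.mean(out**2))
    if rms > 0:
        out *= SNORE_BURST_RMS / rms
    return out


def _noise_burst(rng: np.random.Generator, rate: float, dur_s: float, amp_rms: float) -> np.ndarray:
    n = int(round(dur_s * rate))
    sos = signal.butter(4, [50.0, 2000.0], btype="bandpass", fs=rate, output="sos")
    out = signal.sosfilt(sos, rng.standard_normal(n))
    out *= tukey(n, alpha=0.4)
    rms = np.sqrt(np.mean(out**2))
    if rms > 0:
        out *= amp_rms / rms
    return out


def _place(minute: np.ndarray, burst: np.ndarray, onset_s: float, rate: float) -> None:
    lo = int(round(onset_s * rate))
    hi = min(lo + len(burst), len(minute))
    if hi > lo:
        minute[lo:hi] += burst[: hi - lo]


def gen_normal_minute(seed: int, rate: float = 5000.0) -> np.ndarray:
    """Breathing minute: one loud inspiratory and one weak expiratory burst
    per cycle, cycle period uniform in 3-6 s."""
    if rate < 5000:
        raise ValueError("rate must be >= 5000 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(MINUTE_S * rate))
    minute = np.zeros(n)
    t = rng.uniform(0.2, 0.8)
    while t < MINUTE_S - 1.0:
        period = rng.uniform(3.0, 6.0)
        insp_dur = 0.35 * period
        exp_dur = 0.30 * period
        _place(minute, _noise_burst(rng, rate, insp_dur, NORMAL_BURST_RMS), t, rate)
        _place(
            minute,
            _noise_burst(rng, rate, exp_dur, 0.25 * NORMAL_BURST_RMS),
            t + 0.45 * period,
            rate,
        )
        t += period
    minute += BACKGROUND_NOISE_AMP * rng.standard_normal(n)
    return minute


def gen_simple_snore_minute(
    seed: int,
    rate: float = 5000.0,
    f1_hz: float = 400.0,
    interval_jitter_s: float = 0.2,
    f1_jitter_hz: float = 15.0,
    base_interval_s: float = 4.0,
) -> np.ndarray:
    """Regular snoring: bursts every ~4 s with small F1 and timing jitter."""
    rng = np.random.default_rng(seed)
    n = int(round(MINUTE_S * rate))
    minute = np.zeros(n)
    t = rng.uniform(0.3, 1.0)
    while t < MINUTE_S - BURST_DUR_S:
        f1 = f1_hz + f1_jitter_hz * rng.standard_normal()
        f1 = float(np.clip(f1, 120.0, 2300.0))
        _place(minute, _snore_burst(rng, rate, f1), t, rate)
        t += max(1.8, base_interval_s + interval_jitter_s * rng.standard_normal())
    minute += BACKGROUND_NOISE_AMP * rng.standard_normal(n)
    return minute


def gen_apneic_snore_minute(
    seed: int,
    rate: float = 5000.0,
    f1_hz: float = 600.0,
    pause_s: float = 12.0,
    interval_jitter_s: float = 3.0,
    f1_jitter_hz: float = 100.0,
) -> np.ndarray:
    """Irregular snoring with one inserted silent pause of ``pause_s``.

    One burst is pinned to end exactly at the pause start and the next to
    start exactly at the pause end, so the generated maximum pause equals
    ``pause_s``; all other inter-burst gaps are capped below
    ``min(4.0, pause_s - 1.2)`` so the inserted pause is the maximum.
    """
    if not 0 < pause_s < MINUTE_S - 8:
        raise ValueError("pause_s must be in (0, 52)")
    rng = np.random.default_rng(seed)
    n = int(round(MINUTE_S * rate))
    minute = np.zeros(n)
    gap_cap = min(4.0, max(1.0, pause_s - 1.2))
    pause_start = rng.uniform(8.0, max(9.0, 56.0 - pause_s))
    pause_end = pause_start + pause_s

    def draw_interval() -> float:
        iv = 4.0 + interval_jitter_s * rng.standard_normal()
        return float(np.clip(iv, 1.6, BURST_DUR_S + gap_cap))

    def burst_at(onset: float) -> None:
        f1 = f1_hz + f1_jitter_hz * rng.standard_normal()
        f1 = float(np.clip(f1, 120.0, 2300.0))
        _place(minute, _snore_burst(rng, rate, f1), onset, rate)

    # before the pause: last burst pinned to end at pause_start
    t = pause_start - BURST_DUR_S
    pre_onsets = [t]
    while True:
        t -= draw_interval()
        if t < 0.2:
            break
        pre_onsets.append(t)
    for onset in pre_onsets:
        burst_at(onset)
    # after the pause: first burst starts exactly at pause_end
    t = pause_end
    post_onsets = []
    while t <= MINUTE_S - BURST_DUR_S - 0.1:
        post_onsets.append(t)
        burst_at(t)
        t += draw_interval()
    # keep the trailing gap shorter than the inserted pause
    last_off = (post_onsets[-1] + BURST_DUR_S) if post_onsets else pause_end
    tail_onset = MINUTE_S - BURST_DUR_S - 0.2
    if MINUTE_S - last_off > gap_cap + 1.0 and tail_onset > last_off:
        burst_at(tail_onset)
    minute += BACKGROUND_NOISE_AMP * rng.standard_normal(n)
    return minute


def gen_uncertain_minute(seed: int, rate: float = 5000.0) -> np.ndarray:
    """Near-silent broadband noise, far below the normal-breathing RMS."""
    rng = np.random.default_rng(seed)
    n = int(round(MINUTE_S * rate))
    return UNCERTAIN_NOISE_AMP * rng.standard_normal(n)


def truth_tidal_level(label: str, pause_s: float | None, run_minute: int | None) -> str:
    """Ground-truth level implied by the rule table for a planned minute."""
    if label == "uncertain":
        return "uncertain"
    if label == "normal":
        return "high"
    if label == "apneic":
        return "low" if pause_s > 10.0 else "medium"
    return "medium" if run_minute >= 4 else "high"


def _ss_run_minutes(labels: list[str]) -> list[int | None]:
    out: list[int | None] = []
    run = 0
    for lab in labels:
        if lab == "simple":
            run += 1
            out.append(run)
        else:
            run = 0
            out.append(None)
    return out


def gen_spo2(plan: ScenarioPlan) -> SpO2Trace:
    """1 Hz SpO2 trace whose per-minute minima encode the planned levels.

    Baseline 97 %.  A minute with a planned desaturation ramps down over
    15 s starting at second 10, holds its target, and ramps back up inside
    the same minute, so neighboring minutes keep their own minima.
    """
    run_minutes = _ss_run_minutes(plan.labels)
    values = np.full(plan.n_minutes * 60, SPO2_BASELINE)
    for m, lab in enumerate(plan.labels):
        if lab == "apneic":
            target = (
                SPO2_AS_LONG_PAUSE
                if plan.pause_s[m] > 10.0
                else SPO2_AS_SHORT_PAUSE
            )
        elif lab == "simple" and run_minutes[m] >= 4:
            target = SPO2_SS_LATE
        else:
            continue
        seg = values[m * 60 : (m + 1) * 60]
        seg[10:25] = np.linspace(SPO2_BASELINE, target, 15)
        seg[25:45] = target
        seg[45:60] = np.linspace(target, SPO2_BASELINE, 15)
    return SpO2Trace(values=values)


def gen_scenario(plan: ScenarioPlan) -> tuple[AudioRecording, SpO2Trace, list[dict]]:
    """Concatenated minutes, matching SpO2 trace, and per-minute truth rows.

    Each minute draws its own child seed from the plan seed, so the same
    plan always yields byte-identical audio.
    """
    child_seeds = np.random.SeedSequence(plan.seed).generate_state(plan.n_minutes)
    run_minutes = _ss_run_minutes(plan.labels)
    chunks = []
    truth = []
    for m, lab in enumerate(plan.labels):
        seed = int(child_seeds[m])
        if lab == "normal":
            chunk = gen_normal_minute(seed, plan.rate)
        elif lab == "simple":
            chunk = gen_simple_snore_minute(seed, plan.rate)
        elif lab == "apneic":
            chunk = gen_apneic_snore_minute(seed, plan.rate, pause_s=plan.pause_s[m])
        else:
            chunk = gen_uncertain_minute(seed, plan.rate)
        chunks.append(chunk)
        truth.append(
            {
                "clip_index": m,
                "label": lab,
                "pause_s": plan.pause_s[m],
                "run_minute": run_minutes[m],
                "tidal_level": truth_tidal_level(lab, plan.pause_s[m], run_minutes[m]),
            }
        )
    rec = AudioRecording(samples=np.concatenate(chunks), rate=plan.rate)
    return rec, gen_spo2(plan), truth
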