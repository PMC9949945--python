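"""Breathing-pause analysis and the tidal-volume level rule table.

Apneic clips are scored by the maximum breathing pause interval (MBPI):
pauses longer than 10 s pull the level to low.  Simple-snoring clips are
scored by how long the current snoring run has lasted: from 4 minutes on
the level drops to medium.  Normal clips are high; uncertain clips stay
uncertain.
"""

from __future__ import annotations

from dataclasses import dataclass

from snorevol.preprocess import Clip
from snorevol.formants import short_time_envelope, _supra_threshold_runs

LEVELS = ("high", "medium", "low", "uncertain")


@dataclass
class BreathEventList:
    events: list[tuple[float, float]]  # (onset_s, offset_s), sorted


def detect_breath_events(
    clip: Clip, event_min_ms: float = 200.0
) -> BreathEventList:
    """Supra-threshold respiratory events on the short-time RMS envelope.

    Same relative-threshold detector as the snore-episode finder but with a
    shorter minimum duration so quieter breaths count.  The threshold is
    envelope-relative, so overall gain scaling does not change the result.
    """
    env, frame_s = short_time_envelope(clip.samples, clip.rate)
    runs = _supra_threshold_runs(env, frame_s, event_min_ms / 1000.0)
    return BreathEventList(events=runs)


def mbpi(events: BreathEventList, clip_len_s: float = 60.0) -> float:
    """Maximum breathing pause interval within the clip.

    The maximum over the leading gap (clip start to first onset), all
    inter-event gaps, and the trailing gap (last offset to clip end).  An
    event-free clip is one long pause of the full clip length.
    """
    ev = events.events
    if not ev:
        return float(clip_len_s)
    gaps = [ev[0][0]]
    for (_, prev_off), (next_on, _) in zip(ev[:-1], ev[1:]):
        gaps.append(next_on - prev_off)
    gaps.append(clip_len_s - ev[-1][1])
    return float(max(gaps))


def simple_snoring_elapsed(labels: list[str]) -> dict[int, float]:
    """Elapsed minutes inside each maximal run of simple-snoring clips.

    The k-th consecutive simple-snoring clip gets elapsed = k minutes; any
    other label resets the run.  Keys are clip indices into ``labels``.
    """
    elapsed: dict[int, float] = {}
    run = 0
    for i, lab in enumerate(labels):
        if lab == "simple":
            run += 1
            elapsed[i] = float(run)
        else:
            run = 0
    return elapsed


def tidal_level(
    semantic: str,
    snore_type: str | None = None,
    mbpi_s: float | None = None,
    elapsed_min: float | None = None,
    mbpi_threshold_s: float = 10.0,
    ss_elapsed_threshold_min: float = 4.0,
) -> str:
    """Rule table mapping clip state to a tidal-volume level.

    apneic:  MBPI > 10 s -> low, else medium
    simple:  elapsed >= 4 min -> medium, else high
    normal:  high
    uncertain: uncertain
    """
    if semantic == "uncertain":
        return "uncertain"
    if semantic == "normal":
        return "high"
    if semantic != "snoring":
        raise ValueError(f"unknown semantic label {semantic!r}")
    if snore_type == "apneic":
        if mbpi_s is None:
            raise ValueError("apneic clip requires mbpi_s")
        return "low" if mbpi_s > mbpi_threshold_s else "medium"
    if snore_type == "simple":
        if elapsed_min is None:
            raise ValueError("simple-snoring clip requires elapsed_min")
        return "medium" if elapsed_min >= ss_elapsed_threshold_min else "high"
    raise ValueError(f"snoring clip requires a snore_type, got {snore_type!r}")
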