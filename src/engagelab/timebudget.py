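"""Speech-time budgets: who held the floor, and how much silence there was.

Per window (an event, or a whole session) the features are: speech time
of each speaker group (host / control / participant), the fraction of
speech contributed by participants, and the fraction of the window not
covered by any speech.  Turn speech spans are clipped to the window before
measuring, and bridged merge gaps never count as speech; time not covered
by a speech span of a kept speaker — including noise/over-speak spans,
which were removed upstream — counts as silence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from .praat_io import ValidationError
from .session_model import Session, Turn

__all__ = [
    "TimeFeatures",
    "window_time_features",
    "session_speech_share",
    "turn_length_percentile",
    "speaker_case_share",
]

FractionDenominator = Literal["speech", "window"]


@dataclass(frozen=True)
class TimeFeatures:
    """Time budget of one window (seconds and dimensionless fractions)."""

    host_time: float
    control_time: float
    participant_time: float
    participant_fraction: float  # NaN when the window has no speech
    silence_fraction: float
    window: tuple[float, float]

    @property
    def speech_time(self) -> float:
        return self.host_time + self.control_time + self.participant_time


def _union_length(spans: list[tuple[float, float]]) -> float:
    """Total length of the union of (possibly overlapping) spans."""
    total = 0.0
    end = -math.inf
    for s, e in sorted(spans):
        if s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def _clipped_spans(
    turns: Sequence[Turn], start: float, end: float
) -> list[tuple[float, float, str]]:
    out = []
    for t in turns:
        for s, e in t.spans:
            cs, ce = max(s, start), min(e, end)
            if ce > cs:
                out.append((cs, ce, t.group))
    return out


def window_time_features(
    window: tuple[float, float],
    turns: Sequence[Turn],
    fraction_denominator: FractionDenominator = "speech",
) -> TimeFeatures:
    """Measure the time budget of ``window`` against a turn list.

    ``participant_fraction`` divides by total speech time by default
    (``fraction_denominator="window"`` divides by the window length
    instead); it is NaN when the window holds no speech under the default
    denominator.
    """
    start, end = window
    if end <= start:
        raise ValidationError(f"window end {end} <= start {start}")
    spans = _clipped_spans(turns, start, end)
    by_group = {"host": 0.0, "control": 0.0, "participant": 0.0}
    for s, e, group in spans:
        by_group[group] += e - s
    duration = end - start
    covered = _union_length([(s, e) for s, e, _ in spans])
    speech = sum(by_group.values())
    if fraction_denominator == "window":
        pfrac = by_group["participant"] / duration
    else:
        pfrac = by_group["participant"] / speech if speech > 0 else math.nan
    return TimeFeatures(
        host_time=by_group["host"],
        control_time=by_group["control"],
        participant_time=by_group["participant"],
        participant_fraction=pfrac,
        silence_fraction=1.0 - covered / duration,
        window=(start, end),
    )


def session_speech_share(
    session: Session, window: tuple[float, float] | None = None
) -> dict[str, float]:
    """Per-group share of total speech time over a whole session (percent).

    Returns host_pct / control_pct / participant_pct (of speech time) and
    silence_pct (of the session window).
    """
    win = window if window is not None else session.span
    tf = window_time_features(win, session.turns)
    speech = tf.speech_time
    if speech <= 0:
        return {
            "host_pct": 0.0, "control_pct": 0.0, "participant_pct": 0.0,
            "silence_pct": 100.0 * tf.silence_fraction,
        }
    return {
        "host_pct": 100.0 * tf.host_time / speech,
        "control_pct": 100.0 * tf.control_time / speech,
        "participant_pct": 100.0 * tf.participant_time / speech,
        "silence_pct": 100.0 * tf.silence_fraction,
    }


def turn_length_percentile(turn: Turn, reference: Sequence[Turn]) -> float:
    """Percentile of a turn's extent among a reference set of turns.

    100 x (# reference turns with duration <= this turn's) / N.  The
    longest turn scores 100; with all durations tied, every turn scores
    100 under the <= convention.
    """
    if not reference:
        raise ValidationError("empty reference turn set")
    d = turn.duration
    return 100.0 * sum(1 for t in reference if t.duration <= d) / len(reference)


def speaker_case_share(
    session: Session,
    speaker: str,
    denominator: Literal["speech", "session"] = "speech",
) -> float:
    """Percent of time one speaker spoke in a session.

    Denominator is total speech time (default) or the session window
    length; an absent speaker scores 0.
    """
    spoke = sum(t.speech_time for t in session.turns if t.speaker == speaker)
    if denominator == "session":
        start, end = session.span
        total = end - start
    else:
        total = sum(t.speech_time for t in session.turns)
    return 100.0 * spoke / total if total > 0 else 0.0
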