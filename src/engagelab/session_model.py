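"""Turn structure of a session and its linkage to coded events.

Diarization intervals become ``Turn`` objects: maximal contiguous spans of
speech by one speaker.  Noise (N) and significant over-speak (SO) spans are
removed before anything else happens and never reappear downstream.
Consecutive intervals of the same speaker separated by at most
``merge_gap`` seconds are merged into one turn; the bridged gap is part of
the turn's extent but never counts as speech time (each turn remembers its
source spans).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .praat_io import (
    SPEAKER_LABELS,
    LabeledInterval,
    RawEventRow,
    TimeValueSeries,
    ValidationError,
)

__all__ = [
    "speaker_group",
    "Turn",
    "Session",
    "build_turns",
    "turns_in_event",
    "distinct_speakers",
    "DEFAULT_MERGE_GAP",
]

#: Default gap (s) bridged when merging same-speaker intervals: no bridging.
DEFAULT_MERGE_GAP = 0.0

_GROUPS = {"H": "host", "C": "control", "N": "excluded", "SO": "excluded"}


def speaker_group(code: str) -> str:
    """Map a speaker marker to its group: host, control, participant, excluded."""
    if code in _GROUPS:
        return _GROUPS[code]
    if code in SPEAKER_LABELS:  # F1..F9, M1..M7
        return "participant"
    raise ValidationError(f"unknown speaker code {code!r}")


@dataclass(frozen=True)
class Turn:
    """A maximal contiguous span of one speaker's speech.

    ``spans`` are the source diarization intervals (clipped to nothing);
    their total duration is the turn's speech time, which is <= the turn
    extent ``end - start`` whenever gaps were bridged.
    """

    speaker: str
    start: float
    end: float
    spans: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", float(self.start))
        object.__setattr__(self, "end", float(self.end))
        object.__setattr__(
            self, "spans", tuple((float(s), float(e)) for s, e in self.spans)
        )
        if self.end <= self.start:
            raise ValidationError(f"turn end {self.end} <= start {self.start}")
        group = speaker_group(self.speaker)
        if group == "excluded":
            raise ValidationError(f"turn speaker {self.speaker!r} is an excluded marker")
        if not self.spans:
            object.__setattr__(self, "spans", ((self.start, self.end),))

    @property
    def group(self) -> str:
        return speaker_group(self.speaker)

    @property
    def duration(self) -> float:
        """Extent of the turn (includes any bridged gaps)."""
        return self.end - self.start

    @property
    def speech_time(self) -> float:
        """Actual speech within the turn (bridged gaps excluded)."""
        return sum(e - s for s, e in self.spans)

    def contains_time(self, t: float) -> bool:
        """True if t falls inside a speech span (closed endpoints)."""
        return any(s <= t <= e for s, e in self.spans)


@dataclass
class Session:
    """One recorded group session: turns, events and optional prosody tiers."""

    session_id: str
    turns: list[Turn] = field(default_factory=list)
    events: list[RawEventRow] = field(default_factory=list)
    pitch: TimeValueSeries | None = None
    intensity: TimeValueSeries | None = None
    host_id: int | None = None

    def __post_init__(self) -> None:
        hosts = {e.host_id for e in self.events}
        if len(hosts) > 1:
            raise ValidationError(
                f"session {self.session_id}: events disagree on host id {sorted(hosts)}"
            )
        if hosts:
            event_host = hosts.pop()
            if self.host_id is None:
                self.host_id = event_host
            elif self.host_id != event_host:
                raise ValidationError(
                    f"session {self.session_id}: host_id {self.host_id} inconsistent "
                    f"with event coding (Host {event_host})"
                )

    @property
    def span(self) -> tuple[float, float]:
        """Session window: from 0 to the last annotated/coded instant."""
        ends = [t.end for t in self.turns] + [e.end for e in self.events]
        return (0.0, max(ends)) if ends else (0.0, 0.0)


def build_turns(
    intervals: Sequence[LabeledInterval], merge_gap: float = DEFAULT_MERGE_GAP
) -> list[Turn]:
    """Turn diarization intervals into time-ordered speaker turns.

    N and SO spans are dropped.  After global time-ordering, an interval is
    merged into the previous turn iff it has the same speaker and starts at
    most ``merge_gap`` seconds after that turn ends (an intervening other
    speaker breaks adjacency).  Overlapping intervals of the same speaker
    are a diarization defect and raise.
    """
    kept = sorted(
        (iv for iv in intervals if speaker_group(iv.label) != "excluded"),
        key=lambda iv: (iv.start, iv.end),
    )
    # same-speaker overlap check against that speaker's previous interval
    last_end: dict[str, float] = {}
    for iv in kept:
        prev = last_end.get(iv.label)
        if prev is not None and iv.start < prev:
            raise ValidationError(
                f"overlapping intervals for speaker {iv.label!r} around t={iv.start}"
            )
        last_end[iv.label] = iv.end

    turns: list[Turn] = []
    for iv in kept:
        if (
            turns
            and turns[-1].speaker == iv.label
            and iv.start - turns[-1].end <= merge_gap
        ):
            prev = turns[-1]
            turns[-1] = Turn(
                speaker=prev.speaker,
                start=prev.start,
                end=max(prev.end, iv.end),
                spans=prev.spans + ((iv.start, iv.end),),
            )
        else:
            turns.append(Turn(speaker=iv.label, start=iv.start, end=iv.end))
    return turns


def turns_in_event(event: RawEventRow, turns: Sequence[Turn]) -> list[Turn]:
    """Turns belonging to an event window.

    A turn belongs to the event iff its overlap with [start, end] exceeds
    half the turn's extent (strictly; a turn split exactly 50/50 belongs to
    neither side).  Output preserves time order.
    """
    out = []
    for t in turns:
        overlap = min(t.end, event.end) - max(t.start, event.start)
        if overlap > 0.5 * t.duration:
            out.append(t)
    return out


def distinct_speakers(event: RawEventRow, turns: Sequence[Turn]) -> int:
    """Number of distinct speakers among the event's turns.

    Diagnostic cross-check against the coded "number speaking" column; the
    coded column remains authoritative for modelling.
    """
    return len({t.speaker for t in turns_in_event(event, turns)})
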