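"""Turn-at-Talk graphs: a session's turn structure on a timeline.

One horizontal lane per speaker, one colored segment per turn — host red,
female participants blue, male participants green, the younger control
black — with an optional normalized-pitch trace drawn inside each segment
and optional highlight spans (e.g., unusually long turns).  Every figure
is also emitted as a JSON segment list so structure can be checked
without image comparison.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .praat_io import ValidationError
from .prosody import ZScoredSeries
from .session_model import Session

__all__ = ["SEGMENT_COLORS", "Segment", "turn_at_talk_spec", "turn_at_talk"]


def _speaker_color(code: str) -> str:
    if code == "H":
        return "red"
    if code == "C":
        return "black"
    if code.startswith("F"):
        return "blue"
    if code.startswith("M"):
        return "green"
    raise ValidationError(f"no color for speaker {code!r}")


SEGMENT_COLORS = {"host": "red", "female": "blue", "male": "green", "control": "black"}


@dataclass(frozen=True)
class Segment:
    """One rendered turn: lane, extent and color."""

    speaker: str
    lane: int
    start: float
    end: float
    color: str


def turn_at_talk_spec(
    session: Session, highlights: Sequence[tuple[float, float]] = ()
) -> dict:
    """Deterministic serializable description of the figure.

    Lanes are assigned by first appearance (top lane = first speaker
    heard).  Highlight spans must lie within the session span.
    """
    if not session.turns:
        raise ValidationError(f"session {session.session_id}: no turns to plot")
    t0, t1 = session.span
    lanes: dict[str, int] = {}
    segments: list[Segment] = []
    for turn in session.turns:
        if turn.speaker not in lanes:
            lanes[turn.speaker] = len(lanes)
        for s, e in turn.spans:
            segments.append(
                Segment(
                    speaker=turn.speaker,
                    lane=lanes[turn.speaker],
                    start=s,
                    end=e,
                    color=_speaker_color(turn.speaker),
                )
            )
    for hs, he in highlights:
        if hs < t0 or he > t1:
            raise ValidationError(f"highlight ({hs}, {he}) outside session span {t0, t1}")
    return {
        "session_id": session.session_id,
        "span": [t0, t1],
        "lanes": lanes,
        "segments": [asdict(s) for s in segments],
        "highlights": [list(h) for h in highlights],
    }


def turn_at_talk(
    session: Session,
    out: str | Path,
    highlights: Sequence[tuple[float, float]] = (),
    pitch_z: ZScoredSeries | None = None,
    json_out: str | Path | None = None,
) -> dict:
    """Render the Turn-at-Talk graph to ``out`` (format by extension).

    Returns the serialized segment spec; when ``json_out`` is given the
    spec is also written there.
    """
    spec = turn_at_talk_spec(session, highlights)
    n_lanes = len(spec["lanes"])
    # fixed hash salt keeps SVG clip-path ids (hence bytes) reproducible
    with plt.rc_context({"svg.hashsalt": "engagelab"}):
        return _render(session, spec, n_lanes, out, pitch_z, json_out)


def _render(session, spec, n_lanes, out, pitch_z, json_out):
    fig, ax = plt.subplots(figsize=(12, 1.0 + 0.5 * n_lanes))
    for seg in spec["segments"]:
        ax.broken_barh(
            [(seg["start"], seg["end"] - seg["start"])],
            (seg["lane"] - 0.4, 0.8),
            facecolors=seg["color"],
            edgecolors="none",
        )
    if pitch_z is not None and len(pitch_z.times):
        lane_of = spec["lanes"]
        for seg in spec["segments"]:
            import numpy as np

            lo = np.searchsorted(pitch_z.times, seg["start"])
            hi = np.searchsorted(pitch_z.times, seg["end"], side="right")
            ts = pitch_z.times[lo:hi]
            vs = pitch_z.values[lo:hi]
            ok = ~np.isnan(vs)
            if ok.any():
                # trace drawn inside the segment band, +-3 z mapped to band height
                y = lane_of[seg["speaker"]] + np.clip(vs[ok] / 3.0, -1, 1) * 0.35
                ax.plot(ts[ok], y, color="white", linewidth=0.4, alpha=0.8)
    for hs, he in spec["highlights"]:
        ax.axvspan(hs, he, color="gold", alpha=0.25, zorder=0)
    ax.set_yticks(list(spec["lanes"].values()))
    ax.set_yticklabels(list(spec["lanes"].keys()))
    ax.set_xlabel("session time (s)")
    ax.set_xlim(*spec["span"])
    ax.set_title(f"Turn-at-Talk: {session.session_id}")
    fig.tight_layout()
    fig.savefig(out, metadata=_stable_metadata(Path(out).suffix))
    plt.close(fig)
    if json_out is not None:
        Path(json_out).write_text(json.dumps(spec, indent=2, sort_keys=True))
    return spec


def _stable_metadata(suffix: str) -> dict | None:
    # strip volatile timestamps so identical inputs give identical bytes
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".png":
        return {"Software": None}
    return None
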