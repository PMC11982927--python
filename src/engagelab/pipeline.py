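"""End-to-end assembly: session files to the per-event modelling table.

One row per coded event with the Likert scores, the eight behavior codes,
the host one-hot, the coded number speaking, the time-budget features of
the event window, and (when tiers are available) the six proximity
columns.  This is the table every regression model consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import praat_io
from .entrainment import (
    PROXIMITY_COLUMNS,
    PairMode,
    event_proximity,
    filter_entrainment_events,
)
from .prosody import turn_features, zscore_by_speaker
from .session_model import (
    DEFAULT_MERGE_GAP,
    Session,
    build_turns,
    distinct_speakers,
)
from .timebudget import FractionDenominator, window_time_features

__all__ = ["load_session", "extract_session_features", "extract_features", "FEATURE_TABLE_COLUMNS"]

FEATURE_TABLE_COLUMNS = (
    "session_id", "event_id", "topic", "start_s", "end_s",
    "social", "humor", "game", "cue", "affirm", "disclose", "correct", "nonverbal",
    "number", "host1", "host2", "host3", "host_id",
    "host_time", "control_time", "participant_time",
    "participant_fraction", "silence_fraction",
    *PROXIMITY_COLUMNS.values(), "n_pairs",
    "n_distinct_speakers", "single_speaker",
    "score_r1", "score_r2",
)


def load_session(
    diarization: str | Path,
    events: str | Path,
    pitch: str | Path | None = None,
    intensity: str | Path | None = None,
    session_id: str | None = None,
    merge_gap: float = DEFAULT_MERGE_GAP,
) -> Session:
    """Read one session's files and build its turn structure."""
    intervals = praat_io.read_diarization(diarization)
    event_rows = praat_io.read_event_sheet(events)
    sid = session_id if session_id is not None else Path(events).stem
    return Session(
        session_id=sid,
        turns=build_turns(intervals, merge_gap=merge_gap),
        events=event_rows,
        pitch=praat_io.read_pitch_tier(pitch) if pitch else None,
        intensity=praat_io.read_intensity_tier(intensity) if intensity else None,
    )


def extract_session_features(
    session: Session,
    pair_mode: PairMode = "cross-speaker",
    fraction_denominator: FractionDenominator = "speech",
) -> pd.DataFrame:
    """Compute the full per-event feature table for one session.

    Proximity columns are NaN for single-speaker events and whenever no
    tier data are available; time features are always computed.
    """
    prox_by_event: dict[int, dict[str, float]] = {}
    if session.pitch is not None or session.intensity is not None:
        pitch_z = (
            zscore_by_speaker(session.pitch, session.turns)
            if session.pitch is not None else None
        )
        intensity_z = (
            zscore_by_speaker(session.intensity, session.turns)
            if session.intensity is not None else None
        )
        features = {
            t: turn_features(t, pitch_z, intensity_z) for t in session.turns
        }
        for i, ev in enumerate(session.events):
            prox = event_proximity(
                ev, session.turns, features, pair_mode=pair_mode,
                event_id=f"{session.session_id}:{i}",
            )
            if prox is not None:
                prox_by_event[i] = {
                    col: prox.diffs[f] for f, col in PROXIMITY_COLUMNS.items()
                }
                prox_by_event[i]["n_pairs"] = max(prox.n_pairs.values(), default=0)

    rows = []
    for i, ev in enumerate(session.events):
        tf = window_time_features(
            (ev.start, ev.end), session.turns,
            fraction_denominator=fraction_denominator,
        )
        n_distinct = distinct_speakers(ev, session.turns)
        row: dict[str, object] = {
            "session_id": session.session_id,
            "event_id": f"{session.session_id}:{i}",
            "topic": ev.topic,
            "start_s": ev.start,
            "end_s": ev.end,
            **{c: ev.codes[j] for j, c in enumerate(praat_io.BEHAVIOR_CODES)},
            "number": ev.number_speaking,
            "host1": ev.host_onehot[0],
            "host2": ev.host_onehot[1],
            "host3": ev.host_onehot[2],
            "host_id": ev.host_id,
            "host_time": tf.host_time,
            "control_time": tf.control_time,
            "participant_time": tf.participant_time,
            "participant_fraction": tf.participant_fraction,
            "silence_fraction": tf.silence_fraction,
            "n_distinct_speakers": n_distinct,
            "single_speaker": int(n_distinct < 2),
            "score_r1": ev.score_r1,
            "score_r2": ev.score_r2 if ev.score_r2 is not None else math.nan,
        }
        prox = prox_by_event.get(i)
        for col in (*PROXIMITY_COLUMNS.values(), "n_pairs"):
            row[col] = prox[col] if prox is not None else math.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_TABLE_COLUMNS))


def extract_features(
    sessions: list[Session],
    pair_mode: PairMode = "cross-speaker",
    fraction_denominator: FractionDenominator = "speech",
) -> pd.DataFrame:
    """Concatenate per-session feature tables over a whole study."""
    frames = [
        extract_session_features(
            s, pair_mode=pair_mode, fraction_denominator=fraction_denominator
        )
        for s in sessions
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(FEATURE_TABLE_COLUMNS)
    )
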