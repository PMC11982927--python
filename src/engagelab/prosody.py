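"""Per-speaker prosody normalization and the six turn-level features.

Absolute pitch and intensity are dominated by anatomy and recording setup,
so before speakers can be compared every pitch/intensity sample is
converted to a Z score per speaker per session: (value - mean) / sd, with
mean and sd computed over all of that speaker's in-turn samples in the
session (sample sd, n-1, by default).  A turn then contributes six
features: mean, max and min of normalized pitch and of normalized
intensity over the samples falling inside the turn (closed interval).

Pitch samples exist only where the voice is voiced; a turn with no voiced
sample yields missing (NaN) pitch features, a value state rather than an
error, and such turns drop out pairwise downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .praat_io import TimeValueSeries
from .session_model import Turn

__all__ = ["TurnProsody", "ZScoredSeries", "zscore_by_speaker", "turn_features"]

PITCH_FEATURES = ("mean_pitch", "max_pitch", "min_pitch")
INTENSITY_FEATURES = ("mean_intensity", "max_intensity", "min_intensity")
FEATURE_NAMES = PITCH_FEATURES + INTENSITY_FEATURES


@dataclass(frozen=True)
class TurnProsody:
    """Six turn-level acoustic features in Z-score units.

    Either signal's triple may be NaN (missing) when the turn has no
    usable samples for that signal.
    """

    mean_pitch: float = math.nan
    max_pitch: float = math.nan
    min_pitch: float = math.nan
    mean_intensity: float = math.nan
    max_intensity: float = math.nan
    min_intensity: float = math.nan

    def feature(self, name: str) -> float:
        return getattr(self, name)

    @property
    def missing(self) -> bool:
        """True when no signal produced any feature."""
        return all(math.isnan(self.feature(f)) for f in FEATURE_NAMES)


@dataclass(frozen=True)
class ZScoredSeries:
    """A normalized tier plus per-point attribution.

    ``values`` holds the Z scores; NaN where a point belongs to a speaker
    that could not be normalized (fewer than two samples, or zero sd).
    ``speakers`` holds the owning speaker code per point, or "" for points
    outside every turn — those keep their raw value and are flagged by
    ``outside_turns``.
    """

    kind: str
    times: np.ndarray
    values: np.ndarray
    speakers: tuple[str, ...]
    outside_turns: np.ndarray  # bool per point
    speaker_stats: dict[str, tuple[float, float]]  # code -> (mean, sd)


def _assign_points(
    times: np.ndarray, turns: Sequence[Turn]
) -> tuple[list[str], np.ndarray]:
    """Owner speaker per sample ("" if outside all speech spans).

    With well-formed diarization a sample lies in at most one speaker's
    span; if spans of different speakers do overlap, the earliest-starting
    turn wins, deterministically.
    """
    owners = [""] * len(times)
    order = sorted(range(len(turns)), key=lambda i: turns[i].start)
    for idx in order:
        t = turns[idx]
        for s, e in t.spans:
            lo = np.searchsorted(times, s, side="left")
            hi = np.searchsorted(times, e, side="right")
            for k in range(lo, hi):
                if owners[k] == "":
                    owners[k] = t.speaker
    outside = np.array([o == "" for o in owners])
    return owners, outside


def zscore_by_speaker(
    series: TimeValueSeries,
    turns: Sequence[Turn],
    ddof: int = 1,
) -> ZScoredSeries:
    """Normalize a tier per speaker over the session.

    ``ddof=1`` (sample sd) is the default; ``ddof=0`` gives population sd
    for sensitivity checks.  Speakers with fewer than two in-turn samples,
    or with zero spread, cannot be normalized: their points become NaN and
    a warning is emitted for the zero-sd case.
    """
    times = np.asarray(series.times, dtype=float)
    raw = np.asarray(series.values, dtype=float)
    owners, outside = _assign_points(times, turns)
    values = raw.copy()
    stats: dict[str, tuple[float, float]] = {}
    for code in sorted({o for o in owners if o}):
        mask = np.array([o == code for o in owners])
        pts = raw[mask]
        if len(pts) < 1 + ddof or len(pts) < 2:
            values[mask] = np.nan
            stats[code] = (math.nan, math.nan)
            continue
        mean = float(np.mean(pts))
        sd = float(np.std(pts, ddof=ddof))
        if sd == 0.0:
            warnings.warn(
                f"speaker {code}: zero {series.kind} spread in session "
                f"{series.session_id!r}; cannot normalize",
                stacklevel=2,
            )
            values[mask] = np.nan
            stats[code] = (mean, 0.0)
            continue
        values[mask] = (pts - mean) / sd
        stats[code] = (mean, sd)
    return ZScoredSeries(
        kind=series.kind,
        times=times,
        values=values,
        speakers=tuple(owners),
        outside_turns=outside,
        speaker_stats=stats,
    )


def _span_stats(turn: Turn, z: ZScoredSeries | None) -> tuple[float, float, float]:
    if z is None or len(z.times) == 0:
        return (math.nan, math.nan, math.nan)
    lo = np.searchsorted(z.times, turn.start, side="left")
    hi = np.searchsorted(z.times, turn.end, side="right")  # closed interval
    vals = z.values[lo:hi]
    # points inside the extent but outside any speech span (bridged gaps)
    # kept their raw value; they must not leak into normalized features
    vals = vals[~z.outside_turns[lo:hi]]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return (math.nan, math.nan, math.nan)
    return (float(np.mean(vals)), float(np.max(vals)), float(np.min(vals)))


def turn_features(
    turn: Turn,
    pitch_z: ZScoredSeries | None,
    intensity_z: ZScoredSeries | None,
) -> TurnProsody:
    """Mean/max/min of normalized pitch and intensity within a turn.

    Samples with time in [turn.start, turn.end] (closed) contribute;
    NaN samples (un-normalizable speakers) are ignored.  A signal with no
    contributing sample yields NaN for its three features.
    """
    p_mean, p_max, p_min = _span_stats(turn, pitch_z)
    i_mean, i_max, i_min = _span_stats(turn, intensity_z)
    return TurnProsody(
        mean_pitch=p_mean, max_pitch=p_max, min_pitch=p_min,
        mean_intensity=i_mean, max_intensity=i_max, min_intensity=i_min,
    )
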