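"""Acoustic-prosodic proximity: how similar sequential turns sound.

Proximity-style entrainment asks whether interlocutors' prosody is close
in feature space.  Per event, for each of the six turn-level features, the
statistic is the mean absolute difference across sequential pairs of turns
inside the event — one number per feature per event, smaller meaning more
entrained.  By default only pairs of *different* speakers count (a
same-speaker adjacent pair measures self-consistency, not entrainment);
``pair_mode="all"`` keeps every adjacent pair for sensitivity analysis.

Events whose window contains turns from fewer than two distinct speakers
carry no between-speaker information and are excluded from the modelling
subset — an expected data condition, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .praat_io import RawEventRow
from .prosody import FEATURE_NAMES, TurnProsody
from .session_model import Turn, turns_in_event

__all__ = [
    "ProximityResult",
    "sequential_pairs",
    "event_proximity",
    "filter_entrainment_events",
    "proximity_table",
    "PairMode",
]

PairMode = Literal["cross-speaker", "all"]

#: Column names used when proximity results are tabulated.
PROXIMITY_COLUMNS = {
    "mean_pitch": "d_mean_pitch",
    "max_pitch": "d_max_pitch",
    "min_pitch": "d_min_pitch",
    "mean_intensity": "d_mean_int",
    "max_intensity": "d_max_int",
    "min_intensity": "d_min_int",
}


@dataclass(frozen=True)
class ProximityResult:
    """Per-event proximity: one mean |difference| per acoustic feature.

    ``diffs[f]`` is NaN when no pair had both sides observed for feature
    ``f``; ``n_pairs[f]`` counts the pairs that contributed.
    """

    event_id: str
    diffs: dict[str, float]
    n_pairs: dict[str, int]

    def __post_init__(self) -> None:
        for f in FEATURE_NAMES:
            d = self.diffs.get(f, math.nan)
            if not math.isnan(d) and d < 0:
                raise ValueError(f"negative proximity diff for {f}")

    @property
    def valid(self) -> bool:
        """At least one feature produced a number."""
        return any(not math.isnan(self.diffs.get(f, math.nan)) for f in FEATURE_NAMES)


def sequential_pairs(
    turns: Sequence[Turn], pair_mode: PairMode = "cross-speaker"
) -> list[tuple[Turn, Turn]]:
    """Adjacent turn pairs (t_i, t_{i+1}) of a time-ordered turn list.

    With the default ``cross-speaker`` mode, adjacent pairs sharing a
    speaker are skipped.  Fewer than two turns give an empty list.
    """
    pairs = []
    for a, b in zip(turns, turns[1:]):
        if pair_mode == "all" or a.speaker != b.speaker:
            pairs.append((a, b))
    return pairs


def event_proximity(
    event: RawEventRow,
    turns: Sequence[Turn],
    features: dict[Turn, TurnProsody],
    pair_mode: PairMode = "cross-speaker",
    event_id: str | None = None,
) -> ProximityResult | None:
    """Mean absolute sequential-pair feature difference for one event.

    Returns None for events with fewer than two distinct speakers among
    their turns (the excluded-single-speaker signal).  Pairs with a missing
    feature on either side are dropped per feature, not per event.
    """
    ev_turns = turns_in_event(event, turns)
    if len({t.speaker for t in ev_turns}) < 2:
        return None
    eid = event_id if event_id is not None else event.topic
    diffs: dict[str, float] = {}
    n_pairs: dict[str, int] = {}
    pairs = sequential_pairs(ev_turns, pair_mode)
    for f in FEATURE_NAMES:
        acc, n = 0.0, 0
        for a, b in pairs:
            fa = features[a].feature(f)
            fb = features[b].feature(f)
            if math.isnan(fa) or math.isnan(fb):
                continue
            acc += abs(fb - fa)
            n += 1
        diffs[f] = acc / n if n else math.nan
        n_pairs[f] = n
    return ProximityResult(event_id=eid, diffs=diffs, n_pairs=n_pairs)


@dataclass
class EntrainmentFilterReport:
    """Bookkeeping from selecting the entrainment modelling subset."""

    kept: list[tuple[RawEventRow, ProximityResult]] = field(default_factory=list)
    n_excluded_single_speaker: int = 0
    n_excluded_missing: int = 0

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_total(self) -> int:
        return self.n_kept + self.n_excluded_single_speaker + self.n_excluded_missing


def filter_entrainment_events(
    events_with_proximity: Iterable[tuple[RawEventRow, ProximityResult | None]],
) -> EntrainmentFilterReport:
    """Keep events with a usable proximity result; count the exclusions.

    ``None`` marks single-speaker events; a result with no finite feature
    (all pairs missing) is excluded as missing.
    """
    report = EntrainmentFilterReport()
    for event, prox in events_with_proximity:
        if prox is None:
            report.n_excluded_single_speaker += 1
        elif not prox.valid:
            report.n_excluded_missing += 1
        else:
            report.kept.append((event, prox))
    return report


def proximity_table(results: Iterable[ProximityResult]) -> pd.DataFrame:
    """Tabulate proximity results (events x d_* feature columns)."""
    rows = []
    for r in results:
        row: dict[str, object] = {"event_id": r.event_id}
        for f, col in PROXIMITY_COLUMNS.items():
            row[col] = r.diffs.get(f, math.nan)
        row["n_pairs"] = max(r.n_pairs.values(), default=0)
        rows.append(row)
    return pd.DataFrame(rows, columns=["event_id", *PROXIMITY_COLUMNS.values(), "n_pairs"])
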