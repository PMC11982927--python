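"""Shared fixtures: hand-built sessions and a small synthetic dataset."""

from __future__ import annotations

import numpy as np
import pytest

from engagelab.praat_io import LabeledInterval, RawEventRow
from engagelab.session_model import Session, Turn, build_turns
from engagelab.synthetic import SyntheticConfig, generate_dataset


def make_event(
    start: float,
    end: float,
    topic: str = "t",
    codes=(0,) * 8,
    number: int = 1,
    host=(1, 0, 0),
    score: int = 3,
    score_r2: int | None = None,
) -> RawEventRow:
    return RawEventRow(
        topic=topic, start=start, end=end, codes=tuple(codes),
        number_speaking=number, host_onehot=tuple(host),
        score_r1=score, score_r2=score_r2,
    )


@pytest.fixture
def simple_turns() -> list[Turn]:
    """H then F1 then H, alternating, inside a 100 s window."""
    return [
        Turn(speaker="H", start=0.0, end=10.0),
        Turn(speaker="F1", start=12.0, end=20.0),
        Turn(speaker="H", start=22.0, end=30.0),
    ]


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """Small, fast study: 4 sessions, one per host, with tiers."""
    return SyntheticConfig(
        n_sessions=4,
        sessions_per_host=(1, 1, 1, 1),
        events_mean=18.0,
        events_min=6,
        events_max=40,
        target_session_s=400.0,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config, seed=0)


def random_intervals(rng: np.random.Generator, n: int, speakers=("H", "C", "F1", "M2")):
    """Non-overlapping labeled intervals with random speakers and gaps."""
    out = []
    t = 0.0
    for _ in range(n):
        t += float(rng.uniform(0.0, 2.0))
        dur = float(rng.uniform(0.5, 5.0))
        out.append(
            LabeledInterval(start=t, end=t + dur, label=str(rng.choice(speakers)))
        )
        t += dur
    return out
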