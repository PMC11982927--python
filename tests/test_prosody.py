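"""Z-normalization and turn-feature extraction against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from engagelab.praat_io import TimeValueSeries
from engagelab.prosody import turn_features, zscore_by_speaker
from engagelab.session_model import Turn


def series(times, values, kind="intensity"):
    return TimeValueSeries(kind=kind, times=tuple(times), values=tuple(values))


def test_zscore_single_speaker_123():
    s = series([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    z = zscore_by_speaker(s, [Turn(speaker="H", start=0, end=4)])
    assert z.values == pytest.approx([-1.0, 0.0, 1.0])  # sample sd = 1


def test_zscore_population_sd_option():
    s = series([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    z = zscore_by_speaker(s, [Turn(speaker="H", start=0, end=4)], ddof=0)
    sd = math.sqrt(2.0 / 3.0)
    assert z.values == pytest.approx([-1 / sd, 0.0, 1 / sd])


def test_zscore_constant_values_missing_with_warning():
    s = series([0.0, 1.0, 2.0], [5.0, 5.0, 5.0])
    with pytest.warns(UserWarning, match="zero intensity spread"):
        z = zscore_by_speaker(s, [Turn(speaker="H", start=0, end=3)])
    assert np.isnan(z.values).all()


def test_zscore_single_point_speaker_missing():
    s = series([0.0, 5.0, 6.0], [10.0, 1.0, 3.0])
    turns = [Turn(speaker="H", start=0, end=1), Turn(speaker="F1", start=4.5, end=7)]
    z = zscore_by_speaker(s, turns)
    assert math.isnan(z.values[0])  # H has a single sample
    # F1 samples [1, 3]: mean 2, sample sd sqrt(2)
    assert z.values[1:] == pytest.approx([-1 / math.sqrt(2), 1 / math.sqrt(2)])


def test_zscore_points_outside_turns_flagged_not_normalized():
    s = series([0.0, 10.0], [3.0, 4.0])
    z = zscore_by_speaker(s, [Turn(speaker="H", start=9, end=11)])
    assert z.outside_turns[0] and not z.outside_turns[1]
    assert z.values[0] == 3.0  # untouched raw value


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_zscore_matches_per_speaker_oracle(seed):
    """Two-speaker fixture equals an independent per-speaker mean/sd computation."""
    rng = np.random.default_rng(seed)
    turns = [
        Turn(speaker="H", start=0, end=10),
        Turn(speaker="F1", start=12, end=22),
        Turn(speaker="H", start=24, end=34),
    ]
    times = np.sort(rng.uniform(0, 34, size=40))
    times = np.unique(times)
    vals = rng.normal(60, 5, size=len(times))
    z = zscore_by_speaker(series(times, vals), turns)
    for speaker, spans in [("H", [(0, 10), (24, 34)]), ("F1", [(12, 22)])]:
        mask = np.array([any(s <= t <= e for s, e in spans) for t in times])
        pts = vals[mask]
        if len(pts) < 2:
            continue
        expect = (pts - pts.mean()) / pts.std(ddof=1)
        assert z.values[mask] == pytest.approx(expect, abs=1e-12)


def test_zscore_in_turn_moments_invariant():
    """Per speaker, normalized in-turn samples have mean 0 and sample sd 1."""
    rng = np.random.default_rng(3)
    turns = [Turn(speaker=s, start=10.0 * i, end=10.0 * i + 8)
             for i, s in enumerate(["H", "F1", "M2", "H", "F1", "M2"])]
    times = np.sort(rng.uniform(0, 60, size=200))
    z = zscore_by_speaker(series(np.unique(times), rng.normal(100, 20, len(np.unique(times))), kind="pitch"), turns)
    for speaker in ("H", "F1", "M2"):
        mask = np.array([sp == speaker for sp in z.speakers])
        pts = z.values[mask]
        assert abs(pts.mean()) < 1e-9
        assert abs(pts.std(ddof=1) - 1.0) < 1e-9


def test_zscore_standard_moments_fixed_point():
    """Re-normalizing already mean-0/sd-1 data leaves it unchanged."""
    times = [0.0, 1.0, 2.0, 3.0]
    vals = [-1.5, -0.5, 0.5, 1.5]
    vals = list(np.array(vals) / np.std(vals, ddof=1))
    turns = [Turn(speaker="H", start=0, end=3)]
    z1 = zscore_by_speaker(series(times, vals), turns)
    z2 = zscore_by_speaker(series(times, z1.values), turns)
    assert z2.values == pytest.approx(z1.values, abs=1e-12)


def test_turn_features_constant_and_arithmetic():
    turns = [Turn(speaker="H", start=0, end=10)]
    zc = zscore_by_speaker(series([1.0, 2.0, 3.0], [7.0, 8.0, 9.0]), turns)
    # normalized values are [-1, 0, 1]
    tp = turn_features(turns[0], None, zc)
    assert (tp.mean_intensity, tp.max_intensity, tp.min_intensity) == (0.0, 1.0, -1.0)
    assert math.isnan(tp.mean_pitch)  # no pitch signal supplied


def test_turn_features_direct_values():
    """mean/max/min of points {-1, 0, 2} in span."""
    from engagelab.prosody import ZScoredSeries

    z = ZScoredSeries(
        kind="pitch",
        times=np.array([1.0, 2.0, 3.0, 20.0]),
        values=np.array([-1.0, 0.0, 2.0, 99.0]),
        speakers=("H", "H", "H", "H"),
        outside_turns=np.zeros(4, dtype=bool),
        speaker_stats={},
    )
    tp = turn_features(Turn(speaker="H", start=0, end=5), z, None)
    assert tp.mean_pitch == pytest.approx(1.0 / 3.0)
    assert tp.max_pitch == 2.0
    assert tp.min_pitch == -1.0


def test_turn_with_no_voiced_samples_is_missing():
    turns = [Turn(speaker="H", start=0, end=5), Turn(speaker="F1", start=50, end=60)]
    zc = zscore_by_speaker(series([1.0, 2.0], [100.0, 120.0], kind="pitch"),
                           [turns[0]])
    tp = turn_features(turns[1], zc, None)
    assert tp.missing


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_turn_features_match_exhaustive_scan(seed):
    rng = np.random.default_rng(seed)
    turn = Turn(speaker="H", start=5.0, end=15.0)
    times = np.unique(np.sort(rng.uniform(0, 20, size=60)))
    vals = rng.normal(0, 1, size=len(times))
    from engagelab.prosody import ZScoredSeries

    z = ZScoredSeries(kind="intensity", times=times, values=vals,
                      speakers=("H",) * len(times),
                      outside_turns=np.zeros(len(times), dtype=bool),
                      speaker_stats={})
    tp = turn_features(turn, None, z)
    in_span = vals[(times >= 5.0) & (times <= 15.0)]  # closed interval
    assert tp.mean_intensity == pytest.approx(in_span.mean(), abs=1e-12)
    assert tp.max_intensity == in_span.max()
    assert tp.min_intensity == in_span.min()
    assert tp.min_intensity <= tp.mean_intensity <= tp.max_intensity
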