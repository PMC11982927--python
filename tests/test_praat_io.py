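"""I/O round-trips and validation for tiers, diarization logs and sheets."""

import math

import pytest

from engagelab import praat_io
from engagelab.praat_io import (
    LabeledInterval,
    PraatFormatError,
    RawEventRow,
    TimeValueSeries,
    ValidationError,
    read_diarization,
    read_event_sheet,
    read_intensity_tier,
    read_pitch_tier,
    write_diarization_tsv,
    write_event_sheet,
    write_textgrid,
    write_tier,
)

LONG_PITCH = """File type = "ooTextFile"
Object class = "PitchTier"

xmin = 0
xmax = 0.5
points: size = 2
points [1]:
    number = 0.0
    value = 100
points [2]:
    number = 0.5
    value = 120
"""

SHORT_PITCH = """File type = "ooTextFile"
Object class = "PitchTier"

0
0.5
2
0.0
100
0.5
120
"""

SHORT_INTENSITY = """File type = "ooTextFile"
Object class = "IntensityTier"

0
1
2
0.0
60
1.0
55
"""


@pytest.mark.parametrize("text", [LONG_PITCH, SHORT_PITCH], ids=["long", "short"])
def test_pitch_tier_dialects(tmp_path, text):
    p = tmp_path / "a.PitchTier"
    p.write_text(text)
    s = read_pitch_tier(p)
    assert s.kind == "pitch"
    assert s.points == [(0.0, 100.0), (0.5, 120.0)]


def test_empty_tier_accepted(tmp_path):
    p = tmp_path / "e.PitchTier"
    p.write_text('File type = "ooTextFile"\nObject class = "PitchTier"\n\n0\n1\n0\n')
    assert len(read_pitch_tier(p)) == 0


def test_intensity_tier_allows_nonpositive(tmp_path):
    p = tmp_path / "i.IntensityTier"
    p.write_text(SHORT_INTENSITY.replace("55", "-5"))
    s = read_intensity_tier(p)
    assert s.points == [(0.0, 60.0), (1.0, -5.0)]
    with pytest.raises(ValidationError):
        TimeValueSeries(kind="pitch", times=(0.0,), values=(-5.0,))


def test_malformed_header_names_line(tmp_path):
    p = tmp_path / "bad.PitchTier"
    p.write_text("not a praat file\n0\n1\n0\n")
    with pytest.raises(PraatFormatError, match="line 1"):
        read_pitch_tier(p)


def test_nonincreasing_times_rejected(tmp_path):
    p = tmp_path / "t.PitchTier"
    p.write_text(SHORT_PITCH.replace("0.5\n120", "0.0\n120"))
    with pytest.raises(ValidationError, match="increasing"):
        read_pitch_tier(p)


def test_wrong_class_rejected(tmp_path):
    p = tmp_path / "x.PitchTier"
    p.write_text(SHORT_INTENSITY)
    with pytest.raises(PraatFormatError, match="expected a pitch"):
        read_pitch_tier(p)


@pytest.mark.parametrize("kind,reader", [("pitch", read_pitch_tier),
                                         ("intensity", read_intensity_tier)])
def test_tier_roundtrip(tmp_path, kind, reader):
    orig = TimeValueSeries(
        kind=kind,
        times=(0.0, 0.123456789, 2.5, 7.000001),
        values=(100.0, 97.5, 210.3, 55.5) if kind == "pitch" else (60.0, -2.5, 0.0, 71.1),
        session_id="s",
    )
    p = tmp_path / f"rt.{kind}"
    write_tier(orig, p)
    back = reader(p)
    assert back.points == orig.points  # exact: repr round-trips floats


def test_diarization_tsv_and_textgrid_roundtrip(tmp_path):
    ivs = [
        LabeledInterval(0.0, 10.0, "H"),
        LabeledInterval(10.5, 12.0, "C"),
        LabeledInterval(12.5, 15.25, "F1"),
        LabeledInterval(16.0, 17.0, "M2"),
        LabeledInterval(17.5, 18.0, "N"),
        LabeledInterval(18.5, 19.0, "SO"),
    ]
    tsv = tmp_path / "d.tsv"
    write_diarization_tsv(ivs, tsv)
    assert read_diarization(tsv) == ivs
    tg = tmp_path / "d.TextGrid"
    write_textgrid(ivs, tg)
    assert read_diarization(tg) == ivs  # empty gap tiles dropped on read


def test_diarization_label_counts(tmp_path):
    # hand count: 2 H, 1 each of C, F1, M2, N
    rows = [(0, 1, "H"), (1, 2, "C"), (2, 3, "F1"), (3, 4, "M2"), (4, 5, "N"), (5, 6, "H")]
    p = tmp_path / "d.tsv"
    p.write_text("".join(f"{a}\t{b}\t{l}\n" for a, b, l in rows))
    got = read_diarization(p)
    counts = {}
    for iv in got:
        counts[iv.label] = counts.get(iv.label, 0) + 1
    assert counts == {"H": 2, "C": 1, "F1": 1, "M2": 1, "N": 1}


def test_unknown_label_rejected(tmp_path):
    p = tmp_path / "d.tsv"
    p.write_text("0\t1\tX3\n")
    with pytest.raises(ValidationError, match="X3"):
        read_diarization(p)


def test_interval_end_before_start_rejected(tmp_path):
    p = tmp_path / "d.tsv"
    p.write_text("5\t5\tH\n")
    with pytest.raises(ValidationError):
        read_diarization(p)


def test_short_textgrid_dialect(tmp_path):
    text = (
        'File type = "ooTextFile"\nObject class = "TextGrid"\n\n'
        "0\n10\n<exists>\n1\n"
        '"IntervalTier"\n"speaker"\n0\n10\n3\n'
        '0\n5\n"H"\n5\n6\n""\n6\n10\n"F1"\n'
    )
    p = tmp_path / "s.TextGrid"
    p.write_text(text)
    got = read_diarization(p)
    assert [(iv.start, iv.end, iv.label) for iv in got] == [(0, 5, "H"), (6, 10, "F1")]


# --- event sheets ----------------------------------------------------------

# Two rows as printed in the study's example coding table.
TABLE_ROWS_CSV = (
    "topic,start_s,end_s,social,humor,game,cue,affirm,disclose,correct,nonverbal,"
    "number,host1,host2,host3,score_r1\n"
    '"Boggle intro",0 s,36 s,0,0,1,1,0,0,0,0,1,1,0,0,1\n'
    '"Boggle, set, go!",179 s,1739 s,1,1,1,1,1,0,1,1,7,1,0,0,5\n'
)


def test_event_sheet_table_rows(tmp_path):
    p = tmp_path / "events.csv"
    p.write_text(TABLE_ROWS_CSV)
    rows = read_event_sheet(p)
    assert len(rows) == 2
    intro, boggle = rows
    assert (intro.start, intro.end, intro.number_speaking, intro.score_r1) == (0, 36, 1, 1)
    assert (boggle.start, boggle.end) == (179, 1739)
    assert boggle.codes == (1, 1, 1, 1, 1, 0, 1, 1)
    assert boggle.number_speaking == 7
    assert boggle.host_onehot == (1, 0, 0)
    assert boggle.host_id == 1
    assert boggle.score_r1 == 5


def test_event_sheet_score_out_of_range(tmp_path):
    p = tmp_path / "events.csv"
    p.write_text(TABLE_ROWS_CSV.replace(",0,0,1,1,0,0,0,0,1,1,0,0,1", ",0,0,1,1,0,0,0,0,1,1,0,0,6"))
    with pytest.raises(ValidationError, match="1-5"):
        read_event_sheet(p)


def test_event_sheet_missing_column(tmp_path):
    p = tmp_path / "events.csv"
    p.write_text("topic,start_s,end_s\nfoo,0,1\n")
    with pytest.raises(ValidationError, match="missing required column"):
        read_event_sheet(p)


def test_event_sheet_alias_headers(tmp_path):
    # Table-style headers (Disc., NVerb, #, Score) map onto canonical names
    p = tmp_path / "events.csv"
    p.write_text(
        "Topic,Start time,End time,Social,Humor,Game,Cue,Affirm,Disc.,Correct,NVerb,"
        "#,Host 1,Host 2,Host 3,Score\n"
        "x,0 s,36 s,0,0,1,1,0,0,0,0,1,1,0,0,1\n"
    )
    rows = read_event_sheet(p)
    assert rows[0].end == 36 and rows[0].score_r1 == 1


def test_event_sheet_roundtrip(tmp_path):
    rows = [
        RawEventRow(topic="a, b", start=0.0, end=36.5, codes=(0, 0, 1, 1, 0, 0, 0, 0),
                    number_speaking=1, host_onehot=(1, 0, 0), score_r1=1, score_r2=2),
        RawEventRow(topic="c", start=37.0, end=80.0, codes=(1, 1, 1, 1, 1, 0, 1, 1),
                    number_speaking=7, host_onehot=(0, 0, 0), score_r1=5, score_r2=5),
    ]
    p = tmp_path / "rt.csv"
    write_event_sheet(rows, p)
    assert read_event_sheet(p) == rows


def test_host4_is_all_zero_onehot():
    e = RawEventRow(topic="x", start=0, end=1, codes=(0,) * 8, number_speaking=1,
                    host_onehot=(0, 0, 0), score_r1=3)
    assert e.host_id == 4
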