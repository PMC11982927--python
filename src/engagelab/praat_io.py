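"""Readers and writers for the pipeline's on-disk formats.

Three kinds of artifact are consumed:

* Praat ``PitchTier`` / ``IntensityTier`` text files (both the "short" and
  the long text dialect), holding time-stamped fundamental-frequency (Hz)
  or loudness (dB) samples for one session;
* diarization logs: "who spoke when" as labeled time intervals, either a
  Praat ``TextGrid`` interval tier or a three-column TSV
  (``start<TAB>end<TAB>label``);
* event-coding sheets: one CSV row per coded interaction event with eight
  binary behavior codes, the number of people speaking, a host one-hot and
  one or two Likert engagement scores.

All times are seconds as decimal numbers.  Writers emit the long Praat
dialect; reading back what was written is the identity on valid data.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PraatFormatError",
    "ValidationError",
    "TimeValueSeries",
    "LabeledInterval",
    "RawEventRow",
    "SPEAKER_LABELS",
    "EVENT_SHEET_COLUMNS",
    "read_pitch_tier",
    "read_intensity_tier",
    "write_tier",
    "read_diarization",
    "write_diarization_tsv",
    "write_textgrid",
    "read_event_sheet",
    "write_event_sheet",
]


class PraatFormatError(ValueError):
    """A file does not follow the expected Praat text layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# Speaker markers used by the diarization scheme: one host (H), one younger
# control (C), up to nine female (F1..F9) and seven male (M1..M7) older-adult
# participants, plus N (noise) and SO (significant over-speak) spans that are
# excluded from every analysis.
SPEAKER_LABELS: frozenset[str] = frozenset(
    ["H", "C", "N", "SO"]
    + [f"F{i}" for i in range(1, 10)]
    + [f"M{i}" for i in range(1, 8)]
)


@dataclass(frozen=True)
class TimeValueSeries:
    """Sampled pitch (Hz) or intensity (dB) values over session time.

    Times are strictly increasing; pitch values must be positive (a pitch
    tracker emits values only for voiced frames), intensity may be any
    finite dB value.
    """

    kind: str  # "pitch" | "intensity"
    times: tuple[float, ...]
    values: tuple[float, ...]
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("pitch", "intensity"):
            raise ValidationError(f"unknown series kind {self.kind!r}")
        if len(self.times) != len(self.values):
            raise ValidationError("times and values differ in length")
        prev = None
        for t, v in zip(self.times, self.values):
            if not (t == t and abs(t) != float("inf")):
                raise ValidationError(f"non-finite time {t!r}")
            if not (v == v and abs(v) != float("inf")):
                raise ValidationError(f"non-finite value {v!r} at t={t}")
            if prev is not None and t <= prev:
                raise ValidationError(
                    f"times not strictly increasing at t={t} (previous {prev})"
                )
            if self.kind == "pitch" and v <= 0:
                raise ValidationError(f"non-positive pitch {v} at t={t}")
            prev = t

    def __len__(self) -> int:
        return len(self.times)

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.times, self.values))


@dataclass(frozen=True)
class LabeledInterval:
    """One diarization span: a speaker marker over [start, end)."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", float(self.start))
        object.__setattr__(self, "end", float(self.end))
        if self.end <= self.start:
            raise ValidationError(
                f"interval end {self.end} <= start {self.start} ({self.label!r})"
            )
        if self.label not in SPEAKER_LABELS:
            raise ValidationError(
                f"unknown speaker label {self.label!r}; "
                f"expected one of H, C, F1..F9, M1..M7, N, SO"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


#: Behavior-code column order used throughout the package.
BEHAVIOR_CODES = (
    "social", "humor", "game", "cue", "affirm", "disclose", "correct", "nonverbal",
)

EVENT_SHEET_COLUMNS = (
    "topic", "start_s", "end_s",
    *BEHAVIOR_CODES,
    "number", "host1", "host2", "host3", "score_r1",
)  # score_r2 optional trailing column


@dataclass
class RawEventRow:
    """One coded event: a self-contained interaction segment.

    ``codes`` holds the eight binary behavior flags in ``BEHAVIOR_CODES``
    order.  ``host_onehot`` identifies Hosts 1-3; all zeros means Host 4.
    ``score_r1``/``score_r2`` are the two investigators' 1-5 Likert
    engagement ratings (rater 2 optional).
    """

    topic: str
    start: float
    end: float
    codes: tuple[int, ...]
    number_speaking: int
    host_onehot: tuple[int, int, int]
    score_r1: int
    score_r2: int | None = None

    def __post_init__(self) -> None:
        self.start = float(self.start)
        self.end = float(self.end)
        if self.end <= self.start:
            raise ValidationError(
                f"event {self.topic!r}: end {self.end} <= start {self.start}"
            )
        if len(self.codes) != 8 or any(c not in (0, 1) for c in self.codes):
            raise ValidationError(
                f"event {self.topic!r}: behavior codes must be 8 binary flags"
            )
        if self.number_speaking < 1:
            raise ValidationError(
                f"event {self.topic!r}: number speaking {self.number_speaking} < 1"
            )
        if len(self.host_onehot) != 3 or any(h not in (0, 1) for h in self.host_onehot):
            raise ValidationError(f"event {self.topic!r}: bad host one-hot")
        if sum(self.host_onehot) > 1:
            raise ValidationError(f"event {self.topic!r}: multiple host flags set")
        for name, score in (("score_r1", self.score_r1), ("score_r2", self.score_r2)):
            if score is not None and score not in (1, 2, 3, 4, 5):
                raise ValidationError(
                    f"event {self.topic!r}: {name}={score} outside the 1-5 scale"
                )

    @property
    def host_id(self) -> int:
        """Host number 1-4 (all-zero one-hot encodes Host 4)."""
        for i, flag in enumerate(self.host_onehot, start=1):
            if flag:
                return i
        return 4

    @property
    def duration(self) -> float:
        return self.end - self.start

    def code(self, name: str) -> int:
        return self.codes[BEHAVIOR_CODES.index(name)]


# ---------------------------------------------------------------------------
# Praat real tiers (PitchTier / IntensityTier)
# ---------------------------------------------------------------------------

_TIER_CLASSES = {"PitchTier": "pitch", "IntensityTier": "intensity"}
_NUM_RE = re.compile(r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?")


def _read_text(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return text.splitlines()


def _parse_header(lines: list[str], path: str | Path) -> str:
    """Return the Object class; raise naming the offending line."""
    if not lines or "ooTextFile" not in lines[0]:
        raise PraatFormatError(
            f"{path}: line 1 is not a Praat 'ooTextFile' header: "
            f"{lines[0]!r}" if lines else f"{path}: empty file"
        )
    if len(lines) < 2 or "Object class" not in lines[1]:
        raise PraatFormatError(
            f"{path}: line 2 does not declare an Object class: "
            f"{(lines[1] if len(lines) > 1 else '')!r}"
        )
    m = re.search(r'"([^"]+)"', lines[1])
    if not m:
        raise PraatFormatError(f"{path}: line 2 has no quoted class name")
    return m.group(1)


def _tier_numbers(lines: list[str], path: str | Path) -> list[float]:
    """Extract the numeric payload of a real tier, either dialect.

    Long dialect lines look like ``xmin = 0``, ``points: size = 2``,
    ``number = 0.5``, ``value = 100``; the short dialect is one bare number
    per line.  Both reduce to the same flat sequence
    ``xmin, xmax, n, t1, v1, t2, v2, ...`` once structural noise is dropped.
    """
    out: list[float] = []
    for lineno, raw in enumerate(lines[2:], start=3):
        line = raw.strip()
        if not line:
            continue
        if "=" in line:
            # long dialect: keep the value right of '='; skip pure structure
            key, _, rest = line.partition("=")
            m = _NUM_RE.search(rest)
            if m is None:
                raise PraatFormatError(f"{path}: line {lineno}: no number in {raw!r}")
            out.append(float(m.group(0)))
        elif line.endswith(":") or line.endswith("]:"):
            continue  # "points [1]:" block marker
        else:
            m = _NUM_RE.fullmatch(line)
            if m is None:
                raise PraatFormatError(
                    f"{path}: line {lineno}: expected a number, got {raw!r}"
                )
            out.append(float(line))
    return out


def _read_real_tier(path: str | Path, expected_kind: str) -> TimeValueSeries:
    lines = _read_text(path)
    klass = _parse_header(lines, path)
    kind = _TIER_CLASSES.get(klass)
    if kind is None:
        raise PraatFormatError(f"{path}: Object class {klass!r} is not a real tier")
    if kind != expected_kind:
        raise PraatFormatError(
            f"{path}: expected a {expected_kind} tier, found {klass!r}"
        )
    nums = _tier_numbers(lines, path)
    if len(nums) < 3:
        raise PraatFormatError(f"{path}: truncated tier (need xmin, xmax, size)")
    n = int(nums[2])
    payload = nums[3:]
    if len(payload) != 2 * n:
        raise PraatFormatError(
            f"{path}: declared {n} points but found {len(payload) / 2:g}"
        )
    times = tuple(payload[0::2])
    values = tuple(payload[1::2])
    session_id = Path(path).stem
    return TimeValueSeries(kind=kind, times=times, values=values, session_id=session_id)


def read_pitch_tier(path: str | Path) -> TimeValueSeries:
    """Read a Praat PitchTier (short or long text dialect)."""
    return _read_real_tier(path, "pitch")


def read_intensity_tier(path: str | Path) -> TimeValueSeries:
    """Read a Praat IntensityTier (short or long text dialect)."""
    return _read_real_tier(path, "intensity")


def write_tier(series: TimeValueSeries, path: str | Path) -> None:
    """Write a TimeValueSeries as a long-dialect Praat real tier."""
    klass = "PitchTier" if series.kind == "pitch" else "IntensityTier"
    xmin = series.times[0] if series.times else 0.0
    xmax = series.times[-1] if series.times else 1.0
    buf = io.StringIO()
    buf.write('File type = "ooTextFile"\n')
    buf.write(f'Object class = "{klass}"\n\n')
    buf.write(f"xmin = {float(xmin)!r}\nxmax = {float(xmax)!r}\n")
    buf.write(f"points: size = {len(series)}\n")
    for i, (t, v) in enumerate(zip(series.times, series.values), start=1):
        buf.write(f"points [{i}]:\n    number = {float(t)!r}\n    value = {float(v)!r}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Diarization: TextGrid interval tier or 3-column TSV
# ---------------------------------------------------------------------------

_LONG_INTERVAL_RE = re.compile(
    r"intervals\s*\[\d+\]\s*:\s*\n"
    r"\s*xmin\s*=\s*(" + _NUM_RE.pattern + r")\s*\n"
    r"\s*xmax\s*=\s*(" + _NUM_RE.pattern + r")\s*\n"
    r'\s*text\s*=\s*"(.*)"',
)


def _intervals_from_textgrid(path: str | Path) -> list[tuple[float, float, str]]:
    lines = _read_text(path)
    klass = _parse_header(lines, path)
    if klass != "TextGrid":
        raise PraatFormatError(f"{path}: Object class {klass!r} is not a TextGrid")
    text = "\n".join(lines)
    if "IntervalTier" not in text:
        raise PraatFormatError(f"{path}: TextGrid has no interval tier")
    if any(re.match(r"\s*class\s*=", ln) for ln in lines[2:]):
        # long dialect: regex over interval blocks
        return [
            (float(m.group(1)), float(m.group(2)), m.group(3))
            for m in _LONG_INTERVAL_RE.finditer(text)
        ]
    # short dialect: quoted strings and bare numbers in a fixed order
    body = [ln.strip() for ln in lines[2:] if ln.strip()]
    out: list[tuple[float, float, str]] = []
    i = 0
    while i < len(body):
        if body[i] == '"IntervalTier"':
            # name, xmin, xmax, size, then triples
            try:
                size = int(float(body[i + 4]))
                j = i + 5
                for _ in range(size):
                    xmin, xmax = float(body[j]), float(body[j + 1])
                    label = body[j + 2].strip('"')
                    out.append((xmin, xmax, label))
                    j += 3
                i = j
                continue
            except (IndexError, ValueError) as exc:
                raise PraatFormatError(f"{path}: truncated short TextGrid") from exc
        i += 1
    return out


def read_diarization(path: str | Path) -> list[LabeledInterval]:
    """Read a diarization log (TextGrid interval tier or start/end/label TSV).

    Empty-label intervals (un-annotated stretches of a TextGrid) are
    dropped; every remaining label must belong to the speaker-marker set.
    """
    path = Path(path)
    head = path.read_text(encoding="utf-8").lstrip()
    if head.startswith("File type"):
        triples = _intervals_from_textgrid(path)
    else:
        triples = []
        for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) < 3:
                raise PraatFormatError(
                    f"{path}: line {lineno}: expected start<TAB>end<TAB>label"
                )
            triples.append((float(parts[0]), float(parts[1]), parts[2].strip()))
    return [
        LabeledInterval(start=s, end=e, label=lab)
        for s, e, lab in triples
        if lab != ""
    ]


def write_diarization_tsv(intervals: Sequence[LabeledInterval], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write(f"{iv.start!r}\t{iv.end!r}\t{iv.label}\n")


def write_textgrid(
    intervals: Sequence[LabeledInterval], path: str | Path, tier_name: str = "speaker"
) -> None:
    """Write intervals as a one-tier long-dialect TextGrid.

    Gaps between labeled intervals are written as empty-text intervals so
    the tier tiles [xmin, xmax] the way Praat expects.
    """
    ivs = sorted(intervals, key=lambda iv: iv.start)
    xmin = min((iv.start for iv in ivs), default=0.0)
    xmax = max((iv.end for iv in ivs), default=1.0)
    tiles: list[tuple[float, float, str]] = []
    cursor = xmin
    for iv in ivs:
        if iv.start > cursor:
            tiles.append((cursor, iv.start, ""))
        tiles.append((iv.start, iv.end, iv.label))
        cursor = max(cursor, iv.end)
    buf = io.StringIO()
    buf.write('File type = "ooTextFile"\nObject class = "TextGrid"\n\n')
    buf.write(f"xmin = {xmin!r}\nxmax = {xmax!r}\n")
    buf.write("tiers? <exists>\nsize = 1\nitem []:\n")
    buf.write("    item [1]:\n")
    buf.write('        class = "IntervalTier"\n')
    buf.write(f'        name = "{tier_name}"\n')
    buf.write(f"        xmin = {xmin!r}\n        xmax = {xmax!r}\n")
    buf.write(f"        intervals: size = {len(tiles)}\n")
    for i, (s, e, lab) in enumerate(tiles, start=1):
        buf.write(f"        intervals [{i}]:\n")
        buf.write(f"            xmin = {s!r}\n            xmax = {e!r}\n")
        buf.write(f'            text = "{lab}"\n')
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Event-coding sheets
# ---------------------------------------------------------------------------

# Header aliases seen in hand-maintained sheets; matching is
# case-insensitive after stripping spaces, dots and underscores.
_COLUMN_ALIASES = {
    "topic": "topic",
    "starttime": "start_s", "start": "start_s", "starts": "start_s",
    "endtime": "end_s", "end": "end_s", "ends": "end_s",
    "social": "social", "humor": "humor", "game": "game",
    "gameqa": "game", "cue": "cue", "cuing": "cue", "hostcuing": "cue",
    "affirm": "affirm", "affirmation": "affirm",
    "disclose": "disclose", "disc": "disclose", "selfdisclosure": "disclose",
    "correct": "correct", "correction": "correct", "hostcorrection": "correct",
    "nonverbal": "nonverbal", "nverb": "nonverbal", "nverbal": "nonverbal",
    "number": "number", "num": "number", "#": "number", "numberspeaking": "number",
    "host1": "host1", "host2": "host2", "host3": "host3",
    "score": "score_r1", "scorer1": "score_r1", "score1": "score_r1",
    "scorer2": "score_r2", "score2": "score_r2",
}


def _canon(name: str) -> str:
    return re.sub(r"[\s._\-]", "", name).lower()


def _resolve_columns(header: Sequence[str], path: str | Path) -> dict[str, int]:
    mapping: dict[str, int] = {}
    for idx, name in enumerate(header):
        canon = _COLUMN_ALIASES.get(_canon(name))
        if canon is not None and canon not in mapping:
            mapping[canon] = idx
    missing = [c for c in EVENT_SHEET_COLUMNS if c not in mapping]
    if missing:
        raise ValidationError(
            f"{path}: event sheet is missing required column(s) {missing}; "
            f"header was {list(header)}"
        )
    return mapping


def _number(cell: str, what: str, path: str | Path, lineno: int) -> float:
    # Table-style sheets print times like "179 s"
    m = _NUM_RE.search(cell)
    if m is None:
        raise ValidationError(f"{path}: line {lineno}: bad {what} {cell!r}")
    return float(m.group(0))


def read_event_sheet(path: str | Path) -> list[RawEventRow]:
    """Read a CSV event-coding sheet into validated RawEventRow records."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    return _parse_event_rows(rows, path)


def read_event_sheet_xlsx(path: str | Path, sheet: int | str = 0) -> list[RawEventRow]:
    """Thin adapter for spreadsheet input; requires openpyxl via pandas."""
    import pandas as pd

    df = pd.read_excel(path, sheet_name=sheet, header=0, dtype=object)
    rows = [list(df.columns)] + df.astype(object).fillna("").values.tolist()
    rows = [[("" if c is None else str(c)) for c in r] for r in rows]
    return _parse_event_rows(rows, path)


def _parse_event_rows(rows: list[list[str]], path: str | Path) -> list[RawEventRow]:
    if not rows:
        raise ValidationError(f"{path}: empty event sheet")
    cols = _resolve_columns(rows[0], path)
    has_r2 = "score_r2" in cols
    out: list[RawEventRow] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not any(str(c).strip() for c in row):
            continue
        get = lambda name: str(row[cols[name]]).strip()  # noqa: E731
        codes = tuple(
            int(_number(get(c), c, path, lineno)) for c in BEHAVIOR_CODES
        )
        r2_cell = get("score_r2") if has_r2 else ""
        out.append(
            RawEventRow(
                topic=get("topic"),
                start=_number(get("start_s"), "start time", path, lineno),
                end=_number(get("end_s"), "end time", path, lineno),
                codes=codes,
                number_speaking=int(_number(get("number"), "number", path, lineno)),
                host_onehot=(
                    int(_number(get("host1"), "host1", path, lineno)),
                    int(_number(get("host2"), "host2", path, lineno)),
                    int(_number(get("host3"), "host3", path, lineno)),
                ),
                score_r1=int(_number(get("score_r1"), "score", path, lineno)),
                score_r2=(
                    int(_number(r2_cell, "score_r2", path, lineno)) if r2_cell else None
                ),
            )
        )
    return out


def write_event_sheet(events: Iterable[RawEventRow], path: str | Path) -> None:
    events = list(events)
    has_r2 = any(e.score_r2 is not None for e in events)
    header = list(EVENT_SHEET_COLUMNS) + (["score_r2"] if has_r2 else [])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for e in events:
            row = [e.topic, repr(e.start), repr(e.end), *e.codes,
                   e.number_speaking, *e.host_onehot, e.score_r1]
            if has_r2:
                row.append("" if e.score_r2 is None else e.score_r2)
            w.writerow(row)
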