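"""Data model, validated CSV I/O, and time/fasting filters for sparse
self-tracked lipid timeseries.

The atomic record is a :class:`LipidSample`: one timestamped finger-prick
measurement of total cholesterol (TC), HDL-cholesterol (HDL) or
triglycerides (TG), in mg/dL, with fasting-state and optional context
metadata (hunger score, menstrual cycle day, duplicate-test pairing,
clinical reference value).

All timestamps are naive local clock times at minute resolution; the
analyses are phrased entirely in local time of day, so no timezone
arithmetic is performed anywhere. Clock windows are half-open
``[start, end)`` so that shared boundaries are never double-counted.
A sample at exactly midnight is treated as hour 24 of the *previous*
calendar day (serial within-day schedules run e.g. 06:00–24:00).
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Analyte",
    "LipidSample",
    "ParticipantSeries",
    "CohortTable",
    "TimeWindow",
    "CsvDialect",
    "RowRejection",
    "read_samples",
    "write_samples",
    "filter_fasted_morning",
    "within_day_slices",
    "day_and_hour",
]

#: Physiological plausibility bounds for any analyte, mg/dL.
VALUE_MIN = 0.0
VALUE_MAX = 2000.0

#: Fasted samples must precede this local time ("before 12:00 local time").
NOON = dt.time(12, 0)


class Analyte(str, enum.Enum):
    """The three directly measured lipid analytes (mg/dL)."""

    TC = "TC"
    HDL = "HDL"
    TG = "TG"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class LipidSample:
    """One timestamped lipid measurement with context metadata.

    Parameters
    ----------
    participant_id : str
        Opaque participant identifier.
    timestamp : datetime.datetime
        Naive local timestamp, minute resolution (seconds are rejected).
    analyte : Analyte
        Which lipid was measured.
    value : float
        Concentration in mg/dL; must lie in (0, 2000).
    fasted : bool
        True if self-reported as >=12 h water-only fast.
    hunger : int, optional
        Perceived hunger on the four-point ordinal scale
        0 = not hungry ... 3 = very hungry.
    cycle_day : int, optional
        Menstrual cycle day (1-based).
    pair_id : str, optional
        Links the two halves of a time-paired duplicate QC test.
    reference_value : float, optional
        Time-paired clinical (venous) value in mg/dL, for validity checks.
    """

    participant_id: str
    timestamp: dt.datetime
    analyte: Analyte
    value: float
    fasted: bool = False
    hunger: Optional[int] = None
    cycle_day: Optional[int] = None
    pair_id: Optional[str] = None
    reference_value: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ValueError("participant_id must be non-empty")
        if not isinstance(self.timestamp, dt.datetime):
            raise TypeError("timestamp must be a datetime.datetime")
        if self.timestamp.tzinfo is not None:
            raise ValueError("timestamps are naive local clock times")
        if self.timestamp.second or self.timestamp.microsecond:
            raise ValueError("timestamps carry minute resolution only")
        if not isinstance(self.analyte, Analyte):
            object.__setattr__(self, "analyte", Analyte(self.analyte))
        if not (VALUE_MIN < float(self.value) < VALUE_MAX):
            raise ValueError(
                f"value {self.value} mg/dL outside plausible range "
                f"({VALUE_MIN}, {VALUE_MAX})"
            )
        if self.hunger is not None and self.hunger not in (0, 1, 2, 3):
            raise ValueError("hunger must be an ordinal in {0,1,2,3}")
        if self.cycle_day is not None and self.cycle_day < 1:
            raise ValueError("cycle_day must be >= 1")
        if self.reference_value is not None and not (
            VALUE_MIN < float(self.reference_value) < VALUE_MAX
        ):
            raise ValueError("reference_value outside plausible range")

    @property
    def clock_time(self) -> dt.time:
        return self.timestamp.time()


def day_and_hour(ts: dt.datetime) -> tuple[dt.date, float]:
    """Map a timestamp to (calendar day, hour-of-day in [0, 24]).

    Midnight is assigned to the *ending* day as hour 24.0 so that a
    06:00/12:00/18:00/24:00 serial schedule forms one within-day slice.
    """
    if ts.hour == 0 and ts.minute == 0:
        return ts.date() - dt.timedelta(days=1), 24.0
    return ts.date(), ts.hour + ts.minute / 60.0


@dataclass(frozen=True)
class TimeWindow:
    """Half-open clock-time window [start, end) within one day."""

    start: dt.time
    end: dt.time
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"window start {self.start} must precede end {self.end}")

    def contains(self, t: dt.time) -> bool:
        return self.start <= t < self.end

    @property
    def start_minute(self) -> int:
        return self.start.hour * 60 + self.start.minute

    @property
    def end_minute(self) -> int:
        return self.end.hour * 60 + self.end.minute

    @classmethod
    def from_hours(cls, start_h: float, end_h: float, label: str = "") -> "TimeWindow":
        def _t(h: float) -> dt.time:
            m = int(round(h * 60))
            return dt.time(m // 60, m % 60)

        return cls(_t(start_h), _t(end_h), label)


@dataclass(frozen=True)
class ParticipantSeries:
    """All samples of one participant, sorted by timestamp.

    Duplicate (timestamp, analyte) pairs are rejected: the device cannot
    produce two readings of one analyte in the same minute outside of
    QC pairs, which carry distinct timestamps in the source data.
    """

    participant_id: str
    samples: tuple[LipidSample, ...]
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.samples, key=lambda s: (s.timestamp, s.analyte.value))
        )
        object.__setattr__(self, "samples", ordered)
        seen: set[tuple[dt.datetime, Analyte]] = set()
        for s in ordered:
            if s.participant_id != self.participant_id:
                raise ValueError(
                    f"sample participant {s.participant_id!r} != series "
                    f"{self.participant_id!r}"
                )
            key = (s.timestamp, s.analyte)
            if key in seen:
                raise ValueError(f"duplicate (timestamp, analyte) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[LipidSample]:
        return iter(self.samples)

    def of_analyte(self, analyte: Analyte) -> tuple[LipidSample, ...]:
        analyte = Analyte(analyte)
        return tuple(s for s in self.samples if s.analyte == analyte)


@dataclass
class CohortTable:
    """A collection of participant series with provenance metadata."""

    participants: tuple[ParticipantSeries, ...]
    provenance: str = field(default="", compare=False)
    rejections: tuple["RowRejection", ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        self.participants = tuple(self.participants)
        ids = [p.participant_id for p in self.participants]
        if len(ids) != len(set(ids)):
            raise ValueError("participant_ids must be unique")

    def __iter__(self) -> Iterator[ParticipantSeries]:
        return iter(self.participants)

    def __len__(self) -> int:
        return len(self.participants)

    def get(self, participant_id: str) -> ParticipantSeries:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)

    @property
    def n_samples(self) -> int:
        return sum(len(p) for p in self.participants)

    def iter_samples(self) -> Iterator[LipidSample]:
        for p in self.participants:
            yield from p.samples


@dataclass(frozen=True)
class RowRejection:
    """One rejected input row: 1-based row number (excluding header) + reason."""

    row: int
    reason: str


@dataclass(frozen=True)
class CsvDialect:
    """Column-name mapping and timestamp format for delimited input.

    Defaults follow the package's own flat layout (one row per sample);
    override the column names to ingest differently labelled deposits.
    """

    participant: str = "participant"
    timestamp: str = "timestamp"
    analyte: str = "analyte"
    value: str = "value"
    fasted: str = "fasted"
    hunger: str = "hunger"
    cycle_day: str = "cycle_day"
    pair_id: str = "pair_id"
    reference_value: str = "reference_value"
    timestamp_format: str = "%Y-%m-%d %H:%M"

    @property
    def required(self) -> tuple[str, ...]:
        return (self.participant, self.timestamp, self.analyte, self.value)

    @property
    def all_columns(self) -> tuple[str, ...]:
        return (
            self.participant,
            self.timestamp,
            self.analyte,
            self.value,
            self.fasted,
            self.hunger,
            self.cycle_day,
            self.pair_id,
            self.reference_value,
        )


DEFAULT_DIALECT = CsvDialect()

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}


def _parse_bool(raw: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"unparseable boolean {raw!r}")


def _cell(row: dict, col: str) -> str:
    v = row.get(col)
    return "" if v is None else str(v).strip()


def read_samples(
    path: str | Path, dialect: CsvDialect = DEFAULT_DIALECT
) -> CohortTable:
    """Read a long-format sample CSV into a validated :class:`CohortTable`.

    Rows violating :class:`LipidSample` invariants (out-of-range value,
    unsupported analyte, malformed timestamp, ...) are rejected
    individually, counted on ``cohort.rejections`` and logged; a missing
    *required* column is a configuration error and raises.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in dialect.required if c not in header]
        if missing:
            raise ValueError(f"missing required column(s) {missing} in {path}")
        rows = list(reader)

    by_participant: dict[str, list[LipidSample]] = {}
    rejections: list[RowRejection] = []
    for i, row in enumerate(rows, start=1):
        try:
            sample = _row_to_sample(row, dialect)
        except (ValueError, TypeError, KeyError) as exc:
            rejections.append(RowRejection(i, str(exc)))
            logger.warning("rejected row %d: %s", i, exc)
            continue
        by_participant.setdefault(sample.participant_id, []).append(sample)

    participants = []
    for pid, samples in by_participant.items():
        try:
            participants.append(ParticipantSeries(pid, tuple(samples)))
        except ValueError as exc:
            # duplicate (timestamp, analyte) within a participant: drop the
            # later duplicates row-by-row rather than the whole participant
            kept: list[LipidSample] = []
            seen: set[tuple[dt.datetime, Analyte]] = set()
            for s in samples:
                key = (s.timestamp, s.analyte)
                if key in seen:
                    rejections.append(
                        RowRejection(0, f"duplicate (timestamp, analyte) for {pid}: {key}")
                    )
                    logger.warning("dropped duplicate for %s at %s", pid, key)
                    continue
                seen.add(key)
                kept.append(s)
            participants.append(ParticipantSeries(pid, tuple(kept)))
            del exc
    return CohortTable(
        tuple(participants), provenance=str(path), rejections=tuple(rejections)
    )


def _row_to_sample(row: dict, dialect: CsvDialect) -> LipidSample:
    ts_raw = _cell(row, dialect.timestamp)
    try:
        ts = dt.datetime.strptime(ts_raw, dialect.timestamp_format)
    except ValueError as exc:
        raise ValueError(f"unparseable timestamp {ts_raw!r}: {exc}") from None
    analyte_raw = _cell(row, dialect.analyte)
    try:
        analyte = Analyte(analyte_raw)
    except ValueError:
        raise ValueError(
            f"unsupported analyte {analyte_raw!r} (expected TC, HDL or TG)"
        ) from None
    hunger_raw = _cell(row, dialect.hunger)
    cycle_raw = _cell(row, dialect.cycle_day)
    pair_raw = _cell(row, dialect.pair_id)
    ref_raw = _cell(row, dialect.reference_value)
    return LipidSample(
        participant_id=_cell(row, dialect.participant),
        timestamp=ts,
        analyte=analyte,
        value=float(_cell(row, dialect.value)),
        fasted=_parse_bool(_cell(row, dialect.fasted)),
        hunger=int(hunger_raw) if hunger_raw else None,
        cycle_day=int(cycle_raw) if cycle_raw else None,
        pair_id=pair_raw or None,
        reference_value=float(ref_raw) if ref_raw else None,
    )


def write_samples(
    cohort: CohortTable, path: str | Path, dialect: CsvDialect = DEFAULT_DIALECT
) -> None:
    """Write a cohort as CSV such that ``read_samples`` round-trips it."""
    path = Path(path)
    records = []
    for s in cohort.iter_samples():
        records.append(
            {
                dialect.participant: s.participant_id,
                dialect.timestamp: s.timestamp.strftime(dialect.timestamp_format),
                dialect.analyte: s.analyte.value,
                dialect.value: repr(float(s.value)),
                dialect.fasted: str(s.fasted).lower(),
                dialect.hunger: "" if s.hunger is None else s.hunger,
                dialect.cycle_day: "" if s.cycle_day is None else s.cycle_day,
                dialect.pair_id: "" if s.pair_id is None else s.pair_id,
                dialect.reference_value: ""
                if s.reference_value is None
                else repr(float(s.reference_value)),
            }
        )
    frame = pd.DataFrame.from_records(records, columns=list(dialect.all_columns))
    frame.to_csv(path, index=False)


def filter_fasted_morning(
    series: ParticipantSeries,
    window: TimeWindow = TimeWindow(dt.time(6, 0), dt.time(8, 0), "morning"),
) -> ParticipantSeries:
    """Keep one fasted morning value per analyte per calendar day.

    A fasting morning sample is one self-reported as taken after >=12 h of
    water-only fasting, before 12:00 local time; the analysis window
    (default 06:00-08:00, half-open) must end at or before noon. When a
    morning holds several qualifying samples of one analyte, the earliest
    is retained, making the per-morning value reproducible.
    """
    if window.end > NOON:
        raise ValueError(f"fasted-morning window must end by 12:00, got {window.end}")
    best: dict[tuple[dt.date, Analyte], LipidSample] = {}
    for s in series.samples:
        if not s.fasted or not window.contains(s.clock_time):
            continue
        key = (s.timestamp.date(), s.analyte)
        if key not in best or s.timestamp < best[key].timestamp:
            best[key] = s
    return ParticipantSeries(
        series.participant_id, tuple(best.values()), dict(series.metadata)
    )


def within_day_slices(
    series: ParticipantSeries,
    min_samples: int,
    analyte: Optional[Analyte] = None,
) -> list[ParticipantSeries]:
    """Split a series into per-calendar-day slices with enough coverage.

    A day qualifies when it holds at least ``min_samples`` samples (of
    ``analyte`` when given, else of any analyte); under-sampled days are
    dropped and logged. Midnight samples count as hour 24 of the previous
    day. Slices are returned in day order and, when ``analyte`` is given,
    restricted to that analyte.
    """
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    if analyte is not None:
        analyte = Analyte(analyte)
    by_day: dict[dt.date, list[LipidSample]] = {}
    for s in series.samples:
        day, _ = day_and_hour(s.timestamp)
        by_day.setdefault(day, []).append(s)
    slices: list[ParticipantSeries] = []
    for day in sorted(by_day):
        samples = by_day[day]
        if analyte is not None:
            samples = [s for s in samples if s.analyte == analyte]
        if len(samples) < min_samples:
            logger.info(
                "participant %s day %s dropped: %d < %d samples",
                series.participant_id,
                day,
                len(samples),
                min_samples,
            )
            continue
        slices.append(
            ParticipantSeries(series.participant_id, tuple(samples), dict(series.metadata))
        )
    return slices
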