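"""Clinical risk-category classification and crossing statistics.

A :class:`RiskScheme` holds, per analyte, a strictly increasing list of
boundaries (mg/dL) and one label per band. The boundary convention is
lower-inclusive: ``value < b1`` is the first category, ``b1 <= value < b2``
the second, and so on — consistent with the conventional "<200 vs
200–240 mg/dL" phrasing of total-cholesterol bands. The default scheme is
the standard US cholesterol-education (NCEP ATP III style) banding:

=======  =========================  ==============================
analyte  boundaries (mg/dL)         note
=======  =========================  ==============================
TC       200, 240                   higher is worse
HDL      40, 60                     lower is worse
TG       150, 200, 500              higher is worse
=======  =========================  ==============================

"Crossing a risk category" means one person's samples, grouped either
within a single day or across fasted mornings, fall into two or more
distinct bands of one analyte.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    Analyte,
    CohortTable,
    ParticipantSeries,
    TimeWindow,
    day_and_hour,
    filter_fasted_morning,
    within_day_slices,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RiskScheme",
    "CrossingReport",
    "classify",
    "crossing_report",
    "variability_summary",
]


@dataclass(frozen=True)
class RiskScheme:
    """Ordered risk-category boundaries and labels per analyte."""

    boundaries: Mapping[Analyte, tuple[float, ...]]
    labels: Mapping[Analyte, tuple[str, ...]]
    #: For HDL lower values are worse; recorded for presentation only,
    #: crossing statistics are direction-agnostic.
    higher_is_worse: Mapping[Analyte, bool] = field(
        default_factory=lambda: {Analyte.TC: True, Analyte.HDL: False, Analyte.TG: True}
    )

    def __post_init__(self) -> None:
        bounds = {Analyte(a): tuple(float(b) for b in bs) for a, bs in self.boundaries.items()}
        labels = {Analyte(a): tuple(ls) for a, ls in self.labels.items()}
        object.__setattr__(self, "boundaries", bounds)
        object.__setattr__(self, "labels", labels)
        for analyte, bs in bounds.items():
            if list(bs) != sorted(set(bs)):
                raise ValueError(f"boundaries for {analyte} must be strictly increasing")
            if analyte not in labels or len(labels[analyte]) != len(bs) + 1:
                raise ValueError(
                    f"{analyte}: need exactly {len(bs) + 1} labels for {len(bs)} boundaries"
                )
            if len(labels[analyte]) < 2:
                raise ValueError(f"{analyte}: need >= 2 categories")

    @classmethod
    def ncep_default(cls) -> "RiskScheme":
        return cls(
            boundaries={
                Analyte.TC: (200.0, 240.0),
                Analyte.HDL: (40.0, 60.0),
                Analyte.TG: (150.0, 200.0, 500.0),
            },
            labels={
                Analyte.TC: ("desirable", "borderline-high", "high"),
                Analyte.HDL: ("low", "intermediate", "high"),
                Analyte.TG: ("normal", "borderline-high", "high", "very-high"),
            },
        )

    def category_index(self, analyte: Analyte, value: float) -> int:
        analyte = Analyte(analyte)
        if analyte not in self.boundaries:
            raise ValueError(f"unknown analyte {analyte!r} for this scheme")
        if value <= 0:
            raise ValueError("value must be positive")
        # lower-inclusive: value == boundary belongs to the higher band
        return int(np.searchsorted(self.boundaries[analyte], value, side="right"))

    def classify(self, analyte: Analyte, value: float) -> str:
        analyte = Analyte(analyte)
        idx = self.category_index(analyte, value)
        return self.labels[analyte][idx]

    def to_dict(self) -> dict:
        return {
            a.value: {"boundaries": list(bs), "labels": list(self.labels[a])}
            for a, bs in self.boundaries.items()
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RiskScheme":
        return cls(
            boundaries={Analyte(a): tuple(v["boundaries"]) for a, v in d.items()},
            labels={Analyte(a): tuple(v["labels"]) for a, v in d.items()},
        )


def classify(scheme: RiskScheme, analyte: Analyte, value: float) -> str:
    """Label ``value`` (mg/dL) under the scheme's lower-inclusive banding."""
    return scheme.classify(analyte, value)


@dataclass
class CrossingReport:
    """Per-participant range/crossing records plus cohort percentages.

    ``rows`` has one record per participant x analyte (only participants
    with >= 2 qualifying samples of that analyte); under-sampled
    participants are listed in ``excluded`` and removed from denominators.
    """

    grouping: str
    rows: pd.DataFrame
    excluded: tuple[tuple[str, str, str], ...] = ()  # (participant, analyte, reason)

    def denominator(self, analyte: Analyte) -> int:
        a = Analyte(analyte).value
        return int((self.rows["analyte"] == a).sum())

    def percent_crossed(self, analyte: Analyte) -> float:
        a = Analyte(analyte).value
        sub = self.rows[self.rows["analyte"] == a]
        if len(sub) == 0:
            return float("nan")
        return 100.0 * float(sub["crossed"].mean())

    def percent_crossed_union(self, analytes: Iterable[Analyte]) -> float:
        """Percent of participants crossing in >= 1 of the given analytes."""
        names = {Analyte(a).value for a in analytes}
        sub = self.rows[self.rows["analyte"].isin(names)]
        if len(sub) == 0:
            return float("nan")
        per = sub.groupby("participant")["crossed"].any()
        return 100.0 * float(per.mean())

    def percent_crossed_any(self) -> float:
        return self.percent_crossed_union(
            Analyte(a) for a in self.rows["analyte"].unique()
        )

    def to_summary_dict(self) -> dict:
        analytes = sorted(self.rows["analyte"].unique()) if len(self.rows) else []
        return {
            "grouping": self.grouping,
            "percent_crossed": {
                a: self.percent_crossed(Analyte(a)) for a in analytes
            },
            "percent_crossed_any": self.percent_crossed_any() if analytes else float("nan"),
            "denominators": {a: self.denominator(Analyte(a)) for a in analytes},
            "n_excluded": len(self.excluded),
        }


def _series_stats(
    samples: Sequence, scheme: RiskScheme, analyte: Analyte
) -> Optional[dict]:
    values = [s.value for s in samples]
    if len(values) < 2:
        return None
    cats = {scheme.category_index(analyte, v) for v in values}
    return {
        "n_samples": len(values),
        "min": float(min(values)),
        "max": float(max(values)),
        "range": float(max(values) - min(values)),
        "n_categories": len(cats),
        "categories": tuple(sorted(scheme.labels[analyte][i] for i in cats)),
        "crossed": len(cats) >= 2,
    }


def crossing_report(
    cohort: CohortTable,
    scheme: RiskScheme,
    grouping: str = "within_day",
    window: Optional[TimeWindow] = None,
    min_samples: int = 2,
) -> CrossingReport:
    """Compute per-participant crossing/range statistics for one grouping.

    ``grouping="within_day"`` evaluates each calendar day with at least
    ``min_samples`` samples separately; a participant's record is the
    qualifying day with the largest range, so ``crossed`` is true exactly
    when some single day visits >= 2 categories. ``grouping=
    "across_mornings"`` pools one fasted value per morning (earliest in
    the window, default 06:00-08:00) across days.
    """
    if grouping not in ("within_day", "across_mornings"):
        raise ValueError(f"unknown grouping {grouping!r}")
    analytes = sorted(scheme.boundaries, key=lambda a: a.value)
    records: list[dict] = []
    excluded: list[tuple[str, str, str]] = []
    for series in cohort:
        for analyte in analytes:
            if grouping == "within_day":
                slices = within_day_slices(series, min_samples, analyte)
                best = None
                for sl in slices:
                    st = _series_stats(sl.samples, scheme, analyte)
                    if st is None:
                        continue
                    day, _ = day_and_hour(sl.samples[0].timestamp)
                    st["day"] = day.isoformat()
                    if best is None or st["range"] > best["range"]:
                        best = st
                stats = best
            else:
                kwargs = {} if window is None else {"window": window}
                filtered = filter_fasted_morning(series, **kwargs)
                stats = _series_stats(filtered.of_analyte(analyte), scheme, analyte)
                if stats is not None:
                    stats["day"] = ""
            if stats is None:
                if len(series.of_analyte(analyte)) > 0:
                    excluded.append(
                        (series.participant_id, analyte.value, "<2 qualifying samples")
                    )
                    logger.info(
                        "excluded %s/%s from %s denominators",
                        series.participant_id,
                        analyte.value,
                        grouping,
                    )
                continue
            records.append(
                {"participant": series.participant_id, "analyte": analyte.value, **stats}
            )
    columns = [
        "participant",
        "analyte",
        "n_samples",
        "min",
        "max",
        "range",
        "n_categories",
        "categories",
        "crossed",
        "day",
    ]
    rows = pd.DataFrame.from_records(records, columns=columns)
    return CrossingReport(grouping=grouping, rows=rows, excluded=tuple(excluded))


def variability_summary(report: CrossingReport) -> pd.DataFrame:
    """Median and SD of per-participant ranges, per analyte.

    The dispersion alongside the median is the standard deviation
    (ddof=1) of the per-participant ranges; with a single participant it
    is NaN. Declared explicitly because a bare "median ± x" is ambiguous.
    """
    if len(report.rows) == 0:
        raise ValueError("empty crossing report")
    out = (
        report.rows.groupby("analyte")["range"]
        .agg(
            median_range="median",
            sd_range=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
            n="count",
        )
        .reset_index()
    )
    out.attrs["dispersion"] = "SD of per-participant ranges (ddof=1)"
    return out
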