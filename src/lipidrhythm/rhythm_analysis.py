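"""Daily-rhythm detection chain for sparse within-day lipid profiles.

The chain mirrors how sparse self-collected within-day series are turned
into a testable time-of-day signal:

1. ``to_percent_of_max`` — each qualifying within-day slice (>= 6 samples
   of the analyte) is normalized to percent of that day's maximum and
   linearly interpolated onto a minute grid between its first and last
   observation (no extrapolation); the observed minutes are tracked so
   statistics can be restricted to real samples.
2. ``aggregate`` — per-minute median (or mean) across profiles.
3. ``moving_average`` — centered 2 h moving mean, truncated at the
   profile's extent.
4. ``fit_sum_of_sines`` — bounded sum-of-sines NLLS on the smoothed
   aggregate (default period bounds 10-12 h and 23-25 h) and on each
   individual profile (23-25 h only).
5. ``peak_trough_test`` — Kruskal-Wallis rank test comparing observed
   percent-of-max values pooled in a trough clock window against a peak
   window, preceded by a Kolmogorov-Smirnov normality check that
   motivates the nonparametric choice.

Interpolated minutes feed only the aggregation/visualization path; the
window test uses observed samples exclusively, because interpolated
minutes are not independent observations.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import (
    Analyte,
    CohortTable,
    ParticipantSeries,
    TimeWindow,
    day_and_hour,
    within_day_slices,
)
from .sinefit import SineFitResult, fit_sum_of_sines

logger = logging.getLogger(__name__)

__all__ = [
    "DailyProfile",
    "AggregateProfile",
    "WindowTestResult",
    "RhythmConfig",
    "RhythmReport",
    "to_percent_of_max",
    "aggregate",
    "moving_average",
    "peak_trough_test",
    "rhythm_pipeline",
    "DEFAULT_WINDOWS",
]

#: Default trough/peak clock windows per analyte, chosen from the observed
#: early-morning minima and late-afternoon maxima of the daily profiles.
DEFAULT_WINDOWS: dict[Analyte, tuple[TimeWindow, TimeWindow]] = {
    Analyte.TC: (
        TimeWindow(dt.time(5, 0), dt.time(7, 0), "trough"),
        TimeWindow(dt.time(15, 0), dt.time(17, 0), "peak"),
    ),
    Analyte.TG: (
        TimeWindow(dt.time(9, 0), dt.time(11, 0), "trough"),
        TimeWindow(dt.time(16, 0), dt.time(18, 0), "peak"),
    ),
    Analyte.HDL: (
        TimeWindow(dt.time(5, 0), dt.time(7, 0), "trough"),
        TimeWindow(dt.time(15, 0), dt.time(17, 0), "peak"),
    ),
}

#: Minimum within-day samples for rhythm work; sparser days are excluded.
MIN_RHYTHM_SAMPLES = 6


@dataclass
class DailyProfile:
    """One participant-day normalized to percent of the day's maximum.

    ``minutes`` is a contiguous minute-of-day grid from the first to the
    last observation (midnight samples appear as minute 1440 of the
    previous day); ``values`` are percent-of-max (max over observed
    minutes is exactly 100); ``observed_mask`` marks real samples.
    """

    participant_id: str
    analyte: Analyte
    day: dt.date
    minutes: np.ndarray
    values: np.ndarray
    observed_mask: np.ndarray

    @property
    def observed_minutes(self) -> np.ndarray:
        return self.minutes[self.observed_mask]

    @property
    def observed_values(self) -> np.ndarray:
        return self.values[self.observed_mask]


@dataclass
class AggregateProfile:
    """Per-minute central value pooled across daily profiles.

    ``values`` is NaN at minutes where no profile contributes;
    ``n`` counts contributing profiles per minute.
    """

    minutes: np.ndarray
    values: np.ndarray
    n: np.ndarray
    stat: str = "median"

    @property
    def hours(self) -> np.ndarray:
        return self.minutes / 60.0

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass(frozen=True)
class WindowTestResult:
    """Kruskal-Wallis trough-vs-peak comparison with a normality pretest."""

    trough_window: TimeWindow
    peak_window: TimeWindow
    n_trough: int
    n_peak: int
    statistic: float
    pvalue: float
    normality_pvalue: float
    all_ties: bool = False

    def to_dict(self) -> dict:
        return {
            "trough_window": [str(self.trough_window.start), str(self.trough_window.end)],
            "peak_window": [str(self.peak_window.start), str(self.peak_window.end)],
            "n_trough": self.n_trough,
            "n_peak": self.n_peak,
            "H": self.statistic,
            "p": self.pvalue,
            "normality_p": self.normality_pvalue,
            "all_ties": self.all_ties,
        }


def to_percent_of_max(
    day_slice: ParticipantSeries,
    analyte: Analyte,
    min_samples: int = MIN_RHYTHM_SAMPLES,
) -> Optional[DailyProfile]:
    """Normalize one within-day slice to percent of its maximum.

    Returns ``None`` (and logs the exclusion) when the slice has fewer
    than ``min_samples`` samples of the analyte — sparser days cannot
    support a sine fit. An all-equal day is a valid constant-100 profile.
    """
    analyte = Analyte(analyte)
    samples = day_slice.of_analyte(analyte)
    if len(samples) < min_samples:
        logger.info(
            "excluded %s %s: %d < %d samples",
            day_slice.participant_id,
            analyte.value,
            len(samples),
            min_samples,
        )
        return None
    day, _ = day_and_hour(samples[0].timestamp)
    obs_minutes = np.array(
        [int(round(day_and_hour(s.timestamp)[1] * 60)) for s in samples]
    )
    order = np.argsort(obs_minutes)
    obs_minutes = obs_minutes[order]
    obs_values = np.array([samples[i].value for i in order], dtype=float)
    # divide before scaling so the day's maximum maps to exactly 100.0
    pct = (obs_values / obs_values.max()) * 100.0
    grid = np.arange(obs_minutes[0], obs_minutes[-1] + 1)
    values = np.interp(grid, obs_minutes, pct)
    mask = np.isin(grid, obs_minutes)
    # guard against float drift: observed maxima must be exactly 100
    values[mask] = pct
    return DailyProfile(
        participant_id=day_slice.participant_id,
        analyte=analyte,
        day=day,
        minutes=grid,
        values=values,
        observed_mask=mask,
    )


def aggregate(profiles: Sequence[DailyProfile], stat: str = "median") -> AggregateProfile:
    """Pool profiles into a per-minute central value (median by default)."""
    if not profiles:
        raise ValueError("need at least one profile")
    if stat not in ("median", "mean"):
        raise ValueError(f"unknown aggregation stat {stat!r}")
    lo = min(int(p.minutes[0]) for p in profiles)
    hi = max(int(p.minutes[-1]) for p in profiles)
    grid = np.arange(lo, hi + 1)
    mat = np.full((len(profiles), grid.size), np.nan)
    for i, p in enumerate(profiles):
        mat[i, p.minutes - lo] = p.values
    n = np.sum(~np.isnan(mat), axis=0)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            central = np.nanmedian(mat, axis=0) if stat == "median" else np.nanmean(mat, axis=0)
    return AggregateProfile(minutes=grid, values=central, n=n, stat=stat)


def moving_average(profile: AggregateProfile, window_hours: float = 2.0) -> AggregateProfile:
    """Centered moving mean over defined minutes, truncated at the edges.

    The window spans ``window_hours`` in total (+- half on each side on the
    minute grid); undefined minutes stay undefined and do not contribute.
    """
    if window_hours <= 0:
        raise ValueError("window must be positive")
    half = int(round(window_hours * 60 / 2))
    win = 2 * half + 1
    series = pd.Series(profile.values)
    smooth = series.rolling(window=win, center=True, min_periods=1).mean().to_numpy()
    smooth[np.isnan(profile.values)] = np.nan
    return AggregateProfile(
        minutes=profile.minutes.copy(), values=smooth, n=profile.n.copy(), stat=profile.stat
    )


def _pool_window(profiles: Sequence[DailyProfile], window: TimeWindow) -> np.ndarray:
    vals = []
    for p in profiles:
        m = p.observed_minutes
        v = p.observed_values
        keep = (m >= window.start_minute) & (m < window.end_minute)
        vals.append(v[keep])
    return np.concatenate(vals) if vals else np.array([])


def peak_trough_test(
    profiles: Sequence[DailyProfile],
    trough: TimeWindow,
    peak: TimeWindow,
) -> WindowTestResult:
    """Kruskal-Wallis comparison of observed values in two clock windows.

    Only observed (non-interpolated) percent-of-max values pool into each
    group. A Kolmogorov-Smirnov test of the pooled standardized values
    against the normal distribution is run first and its p recorded — the
    distributional failure it typically shows is why the rank test is the
    primary comparison. Fully tied data yield H = 0 and p = 1, flagged.
    """
    trough_vals = _pool_window(profiles, trough)
    peak_vals = _pool_window(profiles, peak)
    empties = []
    if trough_vals.size < 2:
        empties.append(f"trough {trough.start}-{trough.end}")
    if peak_vals.size < 2:
        empties.append(f"peak {peak.start}-{peak.end}")
    if empties:
        raise ValueError(f"window(s) with <2 observed values: {', '.join(empties)}")

    pooled = np.concatenate([trough_vals, peak_vals])
    sd = np.std(pooled, ddof=1)
    if sd > 0:
        z = (pooled - pooled.mean()) / sd
        normality_p = float(stats.kstest(z, "norm").pvalue)
    else:
        normality_p = float("nan")

    if np.all(pooled == pooled[0]):
        return WindowTestResult(
            trough_window=trough,
            peak_window=peak,
            n_trough=trough_vals.size,
            n_peak=peak_vals.size,
            statistic=0.0,
            pvalue=1.0,
            normality_pvalue=normality_p,
            all_ties=True,
        )
    h, p = stats.kruskal(trough_vals, peak_vals)
    return WindowTestResult(
        trough_window=trough,
        peak_window=peak,
        n_trough=trough_vals.size,
        n_peak=peak_vals.size,
        statistic=float(h),
        pvalue=float(p),
        normality_pvalue=normality_p,
    )


@dataclass(frozen=True)
class RhythmConfig:
    """Tunable knobs of the rhythm pipeline (defaults follow the chain above)."""

    min_samples: int = MIN_RHYTHM_SAMPLES
    stat: str = "median"
    ma_hours: float = 2.0
    aggregate_bounds: tuple[tuple[float, float], ...] = ((10.0, 12.0), (23.0, 25.0))
    individual_bounds: tuple[tuple[float, float], ...] = ((23.0, 25.0),)
    trough: Optional[TimeWindow] = None
    peak: Optional[TimeWindow] = None

    def windows_for(self, analyte: Analyte) -> tuple[TimeWindow, TimeWindow]:
        default_trough, default_peak = DEFAULT_WINDOWS[Analyte(analyte)]
        return (self.trough or default_trough, self.peak or default_peak)


@dataclass
class IndividualFit:
    participant_id: str
    day: dt.date
    fit: SineFitResult


@dataclass
class RhythmReport:
    """Machine-readable result of the full rhythm pipeline for one analyte."""

    analyte: Analyte
    status: str  # "ok" | "empty"
    n_profiles: int
    n_excluded_days: int
    aggregate_profile: Optional[AggregateProfile]
    smoothed_profile: Optional[AggregateProfile]
    aggregate_fit: Optional[SineFitResult]
    window_test: Optional[WindowTestResult]
    individual_fits: tuple[IndividualFit, ...] = ()

    @property
    def degenerate(self) -> bool:
        return self.aggregate_fit is not None and self.aggregate_fit.degenerate

    def individual_fits_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.individual_fits:
            rows.append(
                {
                    "participant": f.participant_id,
                    "day": f.day.isoformat(),
                    "period_h": f.fit.dominant_period,
                    "amplitude_pct": f.fit.amplitudes[f.fit.dominant_component],
                    "adjusted_r2": f.fit.adjusted_r2,
                    "r2": f.fit.r2,
                    "rmse": f.fit.rmse,
                    "sse": f.fit.sse,
                    "n_points": f.fit.n_points,
                    "degenerate": f.fit.degenerate,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "participant",
                "day",
                "period_h",
                "amplitude_pct",
                "adjusted_r2",
                "r2",
                "rmse",
                "sse",
                "n_points",
                "degenerate",
            ],
        )

    def to_dict(self) -> dict:
        out: dict = {
            "analyte": self.analyte.value,
            "status": self.status,
            "n_profiles": self.n_profiles,
            "n_excluded_days": self.n_excluded_days,
        }
        if self.aggregate_fit is not None:
            out["aggregate_fit"] = self.aggregate_fit.to_dict()
            out["aggregate_fit"]["acrophase_h"] = self.aggregate_fit.acrophase_hours()
        if self.window_test is not None:
            out["window_test"] = self.window_test.to_dict()
        if self.individual_fits:
            out["individual_fits"] = self.individual_fits_frame().to_dict(
                orient="records"
            )
            adj = [
                f.fit.adjusted_r2
                for f in self.individual_fits
                if not f.fit.degenerate
            ]
            out["mean_individual_adjusted_r2"] = float(np.mean(adj)) if adj else None
        return out


def rhythm_pipeline(
    cohort: CohortTable,
    analyte: Analyte,
    config: RhythmConfig = RhythmConfig(),
) -> RhythmReport:
    """Run the full chain on every qualifying within-day slice of a cohort."""
    analyte = Analyte(analyte)
    profiles: list[DailyProfile] = []
    n_excluded = 0
    for series in cohort:
        slices = within_day_slices(series, 2, analyte)
        for sl in slices:
            profile = to_percent_of_max(sl, analyte, config.min_samples)
            if profile is None:
                n_excluded += 1
            else:
                profiles.append(profile)
    if not profiles:
        return RhythmReport(
            analyte=analyte,
            status="empty",
            n_profiles=0,
            n_excluded_days=n_excluded,
            aggregate_profile=None,
            smoothed_profile=None,
            aggregate_fit=None,
            window_test=None,
        )

    agg = aggregate(profiles, config.stat)
    smooth = moving_average(agg, config.ma_hours)
    defined = smooth.defined()
    agg_fit = fit_sum_of_sines(
        smooth.hours[defined], smooth.values[defined], config.aggregate_bounds
    )

    trough, peak = config.windows_for(analyte)
    try:
        wtest = peak_trough_test(profiles, trough, peak)
    except ValueError as exc:
        logger.warning("window test skipped: %s", exc)
        wtest = None

    individual: list[IndividualFit] = []
    min_pts = 3 * len(config.individual_bounds) + 1
    for p in profiles:
        if p.observed_minutes.size <= min_pts:
            logger.info(
                "individual fit skipped for %s %s: %d points",
                p.participant_id,
                p.day,
                p.observed_minutes.size,
            )
            continue
        fit = fit_sum_of_sines(
            p.observed_minutes / 60.0, p.observed_values, config.individual_bounds
        )
        individual.append(IndividualFit(p.participant_id, p.day, fit))

    return RhythmReport(
        analyte=analyte,
        status="ok",
        n_profiles=len(profiles),
        n_excluded_days=n_excluded,
        aggregate_profile=agg,
        smoothed_profile=smooth,
        aggregate_fit=agg_fit,
        window_test=wtest,
        individual_fits=tuple(individual),
    )
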