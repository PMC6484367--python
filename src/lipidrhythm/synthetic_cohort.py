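"""Seedable generator of free-living lipid timeseries.

The generator emulates the multi-timescale structure the downstream
analyses assume, so every stage is testable without any data download:

* a daily (circadian-range) multiplicative cosine on TC and TG peaking in
  the late afternoon (acrophase ~16:00) with early-morning minima, scaled
  so the within-day percent-of-maximum fluctuation is ~40% for TC and
  ~34% for TG; HDL carries no daily component (arrhythmic channel);
* an ultradian ~4 h multiplicative cosine on TG, with a perceived-hunger
  channel emitted in antiphase (configurable phase offset);
* an optional menstrual envelope on TC: a rise across the follicular
  phase to a peak near mid-cycle then a fall across the luteal phase,
  spanning ~50 mg/dL peak-to-trough;
* optional additive postprandial TG bumps with exponential decay;
* multiplicative Gaussian measurement noise at the device's ~4.15%
  coefficient of variation, truncated to keep values positive;
* the study's sparse sampling schemes: serial within-day sampling,
  repeated fasted mornings in a clock window, and hourly-waking
  single-subject sampling.

The latent (noiseless) value of analyte ``x`` for a participant with
realized baseline ``B`` is

``L(t) = B * (1 + A_d cos(2 pi (t - phi_d)/P_d))
        * (1 + A_u cos(2 pi (t - phi_u)/P_u)) + M(day) + PP(t)``

where the daily (d) and ultradian (u) factors default to 1 when disabled,
``M`` is the menstrual envelope contribution (0 when disabled) and ``PP``
the postprandial term (TG only). Everything is deterministic for a fixed
seed.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml

from .core_data import Analyte, CohortTable, LipidSample, ParticipantSeries, TimeWindow

__all__ = [
    "RhythmComponent",
    "MenstrualEnvelope",
    "WithinDaySerial",
    "AcrossMornings",
    "HourlyWaking",
    "SimConfig",
    "GroundTruth",
    "ParticipantDraw",
    "PairedTest",
    "ClinicalPair",
    "latent_value",
    "apply_measurement_noise",
    "generate_cohort",
    "generate_paired_tests",
    "generate_clinical_pairs",
]

_TWO_PI = 2.0 * math.pi

#: All simulated calendars start here; analyses use clock time only.
BASE_DATE = dt.date(2024, 1, 1)


@dataclass(frozen=True)
class RhythmComponent:
    """One multiplicative cosine: period (h), relative amplitude, acrophase.

    ``relative_amplitude`` is a dimensionless fraction of baseline in
    [0, 1); ``acrophase`` is the clock hour of the component's peak.
    """

    period: float
    relative_amplitude: float
    acrophase: float

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not (0.0 <= self.relative_amplitude < 1.0):
            raise ValueError("relative_amplitude must be in [0, 1)")

    def factor(self, t_hours: np.ndarray | float) -> np.ndarray | float:
        """Multiplicative factor 1 + A cos(2 pi (t - phi)/P), peak at t=phi."""
        return 1.0 + self.relative_amplitude * np.cos(
            _TWO_PI * (np.asarray(t_hours, dtype=float) - self.acrophase) / self.period
        )

    @property
    def percent_of_max_fluctuation(self) -> float:
        """(max-min)/max of the pure component, = 2A/(1+A)."""
        a = self.relative_amplitude
        return 2.0 * a / (1.0 + a)

    @classmethod
    def from_percent_of_max(
        cls, period: float, fluctuation: float, acrophase: float
    ) -> "RhythmComponent":
        """Build from a target (max-min)/max fluctuation f: A = f/(2-f)."""
        return cls(period, fluctuation / (2.0 - fluctuation), acrophase)


@dataclass(frozen=True)
class MenstrualEnvelope:
    """Additive rise-fall envelope across a menstrual cycle (mg/dL).

    Linear rise from day 1 to ``peak_day`` (near likely ovulation), then a
    fall across the luteal phase back to baseline at cycle end;
    ``range_mgdl`` is the peak-to-trough span.
    """

    cycle_length: int = 28
    peak_day: int = 14
    range_mgdl: float = 50.0
    shape: str = "rise-fall"

    def __post_init__(self) -> None:
        if not (1 <= self.peak_day <= self.cycle_length):
            raise ValueError("peak_day must be within the cycle")
        if self.range_mgdl < 0:
            raise ValueError("range_mgdl must be >= 0")
        if self.shape != "rise-fall":
            raise ValueError("only the rise-fall shape is modelled")

    def contribution(self, cycle_day: int) -> float:
        d = 1 + (cycle_day - 1) % self.cycle_length
        if d <= self.peak_day:
            frac = (d - 1) / max(self.peak_day - 1, 1)
        else:
            frac = max(
                0.0,
                1.0 - (d - self.peak_day) / max(self.cycle_length - self.peak_day, 1),
            )
        return self.range_mgdl * frac


@dataclass(frozen=True)
class WithinDaySerial:
    """Serial within-day sampling at a fixed interval, e.g. 06:00-22:00 hourly."""

    interval_h: float = 1.0
    start_h: float = 6.0
    end_h: float = 22.0
    n_days: int = 1

    def __post_init__(self) -> None:
        if self.end_h <= self.start_h:
            raise ValueError("degenerate scheme: end <= start")
        if self.interval_h <= 0 or self.n_days < 1:
            raise ValueError("interval must be > 0 and n_days >= 1")

    def sample_hours(self, rng: np.random.Generator) -> list[list[float]]:
        n = int(math.floor((self.end_h - self.start_h) / self.interval_h + 1e-9)) + 1
        hours = [self.start_h + i * self.interval_h for i in range(n)]
        return [[24.0 * d + h for h in hours] for d in range(self.n_days)]


@dataclass(frozen=True)
class AcrossMornings:
    """One fasted sample per morning, uniformly placed in a clock window."""

    window: TimeWindow = field(
        default_factory=lambda: TimeWindow(dt.time(6, 0), dt.time(8, 0), "morning")
    )
    n_days: int = 30

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")

    def sample_hours(self, rng: np.random.Generator) -> list[list[float]]:
        lo, hi = self.window.start_minute, self.window.end_minute
        out = []
        for d in range(self.n_days):
            minute = int(rng.integers(lo, hi))
            out.append([24.0 * d + minute / 60.0])
        return out


@dataclass(frozen=True)
class HourlyWaking:
    """Hourly sampling across the waking day (default 05:00-24:00)."""

    start_h: float = 5.0
    end_h: float = 24.0
    n_days: int = 1

    def __post_init__(self) -> None:
        if self.end_h <= self.start_h:
            raise ValueError("degenerate scheme: end <= start")

    def sample_hours(self, rng: np.random.Generator) -> list[list[float]]:
        n = int(math.floor(self.end_h - self.start_h + 1e-9)) + 1
        hours = [self.start_h + i for i in range(n)]
        return [[24.0 * d + h for h in hours] for d in range(self.n_days)]


SamplingScheme = WithinDaySerial | AcrossMornings | HourlyWaking

#: Defaults: daily fluctuation ~40% of max on TC, ~34% on TG (acrophase
#: 16:00), none on HDL; ~4 h ultradian TG pulses.
DEFAULT_DAILY = {
    Analyte.TC: RhythmComponent.from_percent_of_max(24.0, 0.40, 16.0),
    Analyte.HDL: None,
    Analyte.TG: RhythmComponent.from_percent_of_max(24.0, 0.34, 16.0),
}
DEFAULT_BASELINES = {
    Analyte.TC: (185.0, 25.0),
    Analyte.HDL: (55.0, 12.0),
    Analyte.TG: (150.0, 60.0),
}


def _default_daily():
    return dict(DEFAULT_DAILY)


def _default_baselines():
    return dict(DEFAULT_BASELINES)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a synthetic cohort.

    ``baselines`` maps analyte -> (population mean, between-person SD) in
    mg/dL; ``daily`` maps analyte -> daily RhythmComponent (None for an
    arrhythmic channel). ``acrophase_sd_h`` spreads individual daily
    acrophases around the population value. ``hunger_phase_offset`` is in
    radians relative to the TG ultradian component (pi = antiphase).
    """

    n_participants: int = 13
    baselines: dict = field(default_factory=_default_baselines)
    daily: dict = field(default_factory=_default_daily)
    tg_ultradian: Optional[RhythmComponent] = RhythmComponent(4.0, 0.15, 14.0)
    menstrual: Optional[MenstrualEnvelope] = None
    measurement_cv: float = 4.15
    meal_times: tuple[float, ...] = (8.0, 13.0, 19.0)
    postprandial_tg_gain: float = 0.0
    postprandial_decay_h: float = 2.0
    sampling: SamplingScheme = field(default_factory=WithinDaySerial)
    hunger_phase_offset: float = math.pi
    acrophase_sd_h: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measurement_cv < 0:
            raise ValueError("measurement_cv must be >= 0")
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        baselines = {Analyte(k): tuple(v) for k, v in self.baselines.items()}
        daily = {Analyte(k): v for k, v in self.daily.items()}
        object.__setattr__(self, "baselines", baselines)
        object.__setattr__(self, "daily", daily)

    # -- serialization --------------------------------------------------
    def to_yaml(self) -> str:
        d: dict = {
            "n_participants": self.n_participants,
            "measurement_cv": self.measurement_cv,
            "meal_times": list(self.meal_times),
            "postprandial_tg_gain": self.postprandial_tg_gain,
            "postprandial_decay_h": self.postprandial_decay_h,
            "hunger_phase_offset": self.hunger_phase_offset,
            "acrophase_sd_h": self.acrophase_sd_h,
            "seed": self.seed,
            "baselines": {
                a.value: {"mean": m, "sd": s} for a, (m, s) in self.baselines.items()
            },
            "daily": {
                a.value: (
                    None
                    if c is None
                    else {
                        "period": c.period,
                        "relative_amplitude": c.relative_amplitude,
                        "acrophase": c.acrophase,
                    }
                )
                for a, c in self.daily.items()
            },
        }
        d["tg_ultradian"] = (
            None
            if self.tg_ultradian is None
            else {
                "period": self.tg_ultradian.period,
                "relative_amplitude": self.tg_ultradian.relative_amplitude,
                "acrophase": self.tg_ultradian.acrophase,
            }
        )
        if self.menstrual is not None:
            d["menstrual"] = {
                "cycle_length": self.menstrual.cycle_length,
                "peak_day": self.menstrual.peak_day,
                "range_mgdl": self.menstrual.range_mgdl,
            }
        s = self.sampling
        if isinstance(s, WithinDaySerial):
            d["sampling"] = {
                "scheme": "within_day_serial",
                "interval_h": s.interval_h,
                "start_h": s.start_h,
                "end_h": s.end_h,
                "n_days": s.n_days,
            }
        elif isinstance(s, AcrossMornings):
            d["sampling"] = {
                "scheme": "across_mornings",
                "window_start_h": s.window.start_minute / 60.0,
                "window_end_h": s.window.end_minute / 60.0,
                "n_days": s.n_days,
            }
        else:
            d["sampling"] = {
                "scheme": "hourly_waking",
                "start_h": s.start_h,
                "end_h": s.end_h,
                "n_days": s.n_days,
            }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        d = yaml.safe_load(text) or {}
        kwargs: dict = {}
        for key in (
            "n_participants",
            "measurement_cv",
            "postprandial_tg_gain",
            "postprandial_decay_h",
            "hunger_phase_offset",
            "acrophase_sd_h",
            "seed",
        ):
            if key in d:
                kwargs[key] = d[key]
        if "meal_times" in d:
            kwargs["meal_times"] = tuple(d["meal_times"])
        if "baselines" in d:
            kwargs["baselines"] = {
                Analyte(a): (v["mean"], v["sd"]) for a, v in d["baselines"].items()
            }
        if "daily" in d:
            kwargs["daily"] = {
                Analyte(a): (
                    None
                    if v is None
                    else RhythmComponent(
                        v["period"], v["relative_amplitude"], v["acrophase"]
                    )
                )
                for a, v in d["daily"].items()
            }
        if "tg_ultradian" in d:
            v = d["tg_ultradian"]
            kwargs["tg_ultradian"] = (
                None
                if v is None
                else RhythmComponent(v["period"], v["relative_amplitude"], v["acrophase"])
            )
        if "menstrual" in d and d["menstrual"] is not None:
            v = d["menstrual"]
            kwargs["menstrual"] = MenstrualEnvelope(
                cycle_length=v.get("cycle_length", 28),
                peak_day=v.get("peak_day", 14),
                range_mgdl=v.get("range_mgdl", 50.0),
            )
        if "sampling" in d:
            v = dict(d["sampling"])
            scheme = v.pop("scheme")
            if scheme == "within_day_serial":
                kwargs["sampling"] = WithinDaySerial(**v)
            elif scheme == "across_mornings":
                kwargs["sampling"] = AcrossMornings(
                    window=TimeWindow.from_hours(
                        v.get("window_start_h", 6.0), v.get("window_end_h", 8.0), "morning"
                    ),
                    n_days=v.get("n_days", 30),
                )
            elif scheme == "hourly_waking":
                kwargs["sampling"] = HourlyWaking(**v)
            else:
                raise ValueError(f"unknown sampling scheme {scheme!r}")
        return cls(**kwargs)


@dataclass(frozen=True)
class ParticipantDraw:
    """Realized per-participant parameters (the simulation's ground truth)."""

    participant_id: str
    baselines: dict  # Analyte -> mg/dL
    daily: dict  # Analyte -> RhythmComponent | None (realized acrophase)
    tg_ultradian: Optional[RhythmComponent]
    menstrual: Optional[MenstrualEnvelope]


def latent_value(
    config: SimConfig, draw: ParticipantDraw, analyte: Analyte, t_hours: float
) -> float:
    """Noiseless latent concentration at ``t_hours`` since the simulated start.

    Disabled components contribute their identity (factor 1 / addend 0).
    """
    analyte = Analyte(analyte)
    b = draw.baselines[analyte]
    v = b
    daily = draw.daily.get(analyte)
    if daily is not None:
        v = v * daily.factor(t_hours)
    if analyte == Analyte.TG and draw.tg_ultradian is not None:
        v = v * draw.tg_ultradian.factor(t_hours)
    if analyte == Analyte.TC and draw.menstrual is not None:
        v = v + draw.menstrual.contribution(int(t_hours // 24.0) + 1)
    if analyte == Analyte.TG and config.postprandial_tg_gain > 0:
        v = v + _postprandial(
            t_hours,
            config.meal_times,
            config.postprandial_tg_gain,
            config.postprandial_decay_h,
        )
    return float(v)


def _postprandial(
    t_hours: float, meal_times: Sequence[float], gain: float, tau: float
) -> float:
    """Sum of exponentially decaying post-meal bumps (looks back 24 h)."""
    total = 0.0
    day = int(t_hours // 24.0)
    for d in (day - 1, day):
        if d < 0:
            continue
        for m in meal_times:
            tm = 24.0 * d + m
            if t_hours >= tm:
                total += gain * math.exp(-(t_hours - tm) / tau)
    return total


def apply_measurement_noise(
    latent: float, cv: float, rng: np.random.Generator
) -> float:
    """Multiplicative Gaussian noise latent*(1+eps), eps~N(0, cv/100), >0.

    Truncated by redrawing so the measurement stays positive (the device
    cannot report a nonpositive concentration).
    """
    if latent <= 0:
        raise ValueError("latent must be positive")
    if cv == 0:
        return float(latent)
    sigma = cv / 100.0
    for _ in range(1000):
        v = latent * (1.0 + rng.normal(0.0, sigma))
        if v > 0:
            return float(v)
    raise RuntimeError("noise truncation failed to find a positive draw")


def hunger_signal(
    ultradian: Optional[RhythmComponent], phase_offset: float, t_hours: float
) -> float:
    """Continuous hunger proxy: cosine locked to the TG ultradian phase.

    ``phase_offset`` is in radians relative to the ultradian component;
    pi puts peak hunger at the triglyceride trough (antiphase).
    """
    if ultradian is None:
        return 0.0
    return math.cos(
        _TWO_PI * (t_hours - ultradian.acrophase) / ultradian.period + phase_offset
    )


def hunger_ordinal(signal: float) -> int:
    """Discretize a [-1, 1] hunger signal into the four-point scale 0-3."""
    for level, cut in enumerate((-0.5, 0.0, 0.5)):
        if signal < cut:
            return level
    return 3


@dataclass
class GroundTruth:
    """Realized parameters plus on-demand noiseless trajectories."""

    config: SimConfig
    draws: tuple[ParticipantDraw, ...]

    def draw_for(self, participant_id: str) -> ParticipantDraw:
        for d in self.draws:
            if d.participant_id == participant_id:
                return d
        raise KeyError(participant_id)

    def latent(self, participant_id: str, analyte: Analyte, t_hours: float) -> float:
        return latent_value(self.config, self.draw_for(participant_id), analyte, t_hours)

    def latent_trajectory(
        self,
        participant_id: str,
        analyte: Analyte,
        t0_hours: float = 0.0,
        t1_hours: float = 24.0,
        step_minutes: int = 1,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Minute-resolution noiseless trajectory on [t0, t1]; always > 0."""
        draw = self.draw_for(participant_id)
        t = np.arange(t0_hours, t1_hours + 1e-9, step_minutes / 60.0)
        v = np.array([latent_value(self.config, draw, analyte, ti) for ti in t])
        return t, v

    def to_frame(self):
        import pandas as pd

        rows = []
        for d in self.draws:
            for a, b in d.baselines.items():
                comp = d.daily.get(a)
                rows.append(
                    {
                        "participant": d.participant_id,
                        "analyte": a.value,
                        "baseline_mgdl": b,
                        "daily_period_h": None if comp is None else comp.period,
                        "daily_rel_amplitude": None
                        if comp is None
                        else comp.relative_amplitude,
                        "daily_acrophase_h": None if comp is None else comp.acrophase,
                    }
                )
        return pd.DataFrame(rows)


def _draw_participant(
    config: SimConfig, pid: str, rng: np.random.Generator
) -> ParticipantDraw:
    baselines = {}
    for analyte, (mean, sd) in config.baselines.items():
        b = rng.normal(mean, sd)
        while b <= 10.0:  # keep baselines physiologically positive
            b = rng.normal(mean, sd)
        baselines[analyte] = float(b)
    daily = {}
    for analyte, comp in config.daily.items():
        if comp is None:
            daily[analyte] = None
        else:
            shift = rng.normal(0.0, config.acrophase_sd_h)
            daily[analyte] = replace(comp, acrophase=(comp.acrophase + shift) % 24.0)
    # ultradian pulses are not clock-locked across people: random phase
    ultra = config.tg_ultradian
    if ultra is not None:
        ultra = replace(ultra, acrophase=float(rng.uniform(0.0, ultra.period)))
    return ParticipantDraw(
        participant_id=pid,
        baselines=baselines,
        daily=daily,
        tg_ultradian=ultra,
        menstrual=config.menstrual,
    )


def generate_cohort(config: SimConfig) -> tuple[CohortTable, GroundTruth]:
    """Simulate the configured cohort; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    analytes = sorted(config.baselines, key=lambda a: a.value)
    is_morning = isinstance(config.sampling, AcrossMornings)
    is_hourly = isinstance(config.sampling, HourlyWaking)

    participants = []
    draws = []
    for idx in range(config.n_participants):
        pid = f"P{idx + 1:02d}"
        draw = _draw_participant(config, pid, rng)
        draws.append(draw)
        samples: list[LipidSample] = []
        for day_hours in config.sampling.sample_hours(rng):
            for t in day_hours:
                minute_of_sim = int(round(t * 60))
                ts = dt.datetime.combine(BASE_DATE, dt.time(0, 0)) + dt.timedelta(
                    minutes=minute_of_sim
                )
                cycle_day = (
                    int(t // 24.0) % config.menstrual.cycle_length + 1
                    if config.menstrual is not None
                    else None
                )
                hunger = (
                    hunger_ordinal(
                        hunger_signal(draw.tg_ultradian, config.hunger_phase_offset, t)
                    )
                    if is_hourly and draw.tg_ultradian is not None
                    else None
                )
                for analyte in analytes:
                    lat = latent_value(config, draw, analyte, t)
                    val = apply_measurement_noise(lat, config.measurement_cv, rng)
                    samples.append(
                        LipidSample(
                            participant_id=pid,
                            timestamp=ts,
                            analyte=analyte,
                            value=val,
                            fasted=is_morning,
                            hunger=hunger,
                            cycle_day=cycle_day,
                        )
                    )
        participants.append(ParticipantSeries(pid, tuple(samples)))
    cohort = CohortTable(
        tuple(participants), provenance=f"synthetic(seed={config.seed})"
    )
    return cohort, GroundTruth(config=config, draws=tuple(draws))


# -- QC-oriented generators ---------------------------------------------


@dataclass(frozen=True)
class PairedTest:
    """Two self-tests of one analyte taken within ~10 minutes."""

    participant_id: str
    analyte: Analyte
    first: float
    second: float
    pair_id: str


@dataclass(frozen=True)
class ClinicalPair:
    """A self-test taken within 10 minutes of a clinical venous draw."""

    participant_id: str
    analyte: Analyte
    self_value: float
    reference_value: float


def generate_paired_tests(
    config: SimConfig, n_pairs: int, seed: Optional[int] = None
) -> list[PairedTest]:
    """Duplicate self-tests: one latent value measured twice with device noise."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    analytes = sorted(config.baselines, key=lambda a: a.value)
    pairs = []
    for i in range(n_pairs):
        pid = f"P{int(rng.integers(0, max(config.n_participants, 1))) + 1:02d}"
        draw = _draw_participant(config, pid, rng)
        analyte = analytes[int(rng.integers(0, len(analytes)))]
        t = float(rng.uniform(6.0, 22.0))
        lat = latent_value(config, draw, analyte, t)
        pairs.append(
            PairedTest(
                participant_id=pid,
                analyte=analyte,
                first=apply_measurement_noise(lat, config.measurement_cv, rng),
                second=apply_measurement_noise(lat, config.measurement_cv, rng),
                pair_id=f"pair{i + 1:04d}",
            )
        )
    return pairs


def generate_clinical_pairs(
    config: SimConfig, n_pairs: int, seed: Optional[int] = None
) -> list[ClinicalPair]:
    """Self-vs-clinical pairs: reference is the latent value, self adds noise."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    analytes = sorted(config.baselines, key=lambda a: a.value)
    out = []
    for _ in range(n_pairs):
        pid = f"P{int(rng.integers(0, max(config.n_participants, 1))) + 1:02d}"
        draw = _draw_participant(config, pid, rng)
        analyte = analytes[int(rng.integers(0, len(analytes)))]
        t = float(rng.uniform(6.0, 10.0))
        lat = latent_value(config, draw, analyte, t)
        out.append(
            ClinicalPair(
                participant_id=pid,
                analyte=analyte,
                self_value=apply_measurement_noise(lat, config.measurement_cv, rng),
                reference_value=lat,
            )
        )
    return out
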