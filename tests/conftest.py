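import dataclasses
import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from lipidrhythm import Analyte, CohortTable, LipidSample, ParticipantSeries, SimConfig

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_sample(
    pid="P01",
    ts="2024-01-01 08:00",
    analyte="TC",
    value=180.0,
    **kwargs,
):
    return LipidSample(
        participant_id=pid,
        timestamp=dt.datetime.strptime(ts, "%Y-%m-%d %H:%M"),
        analyte=Analyte(analyte),
        value=value,
        **kwargs,
    )


def make_series(pid, specs):
    """specs: iterable of (ts, analyte, value) or (ts, analyte, value, kwargs)."""
    samples = []
    for spec in specs:
        ts, analyte, value = spec[:3]
        kwargs = spec[3] if len(spec) > 3 else {}
        samples.append(make_sample(pid, ts, analyte, value, **kwargs))
    return ParticipantSeries(pid, tuple(samples))


def make_cohort(series_specs):
    """series_specs: dict pid -> specs (see make_series)."""
    return CohortTable(
        tuple(make_series(pid, specs) for pid, specs in series_specs.items())
    )


@pytest.fixture
def default_config():
    return SimConfig()


@pytest.fixture
def noiseless_config():
    return dataclasses.replace(SimConfig(), measurement_cv=0.0)
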