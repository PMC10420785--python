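import dataclasses

import pandas as pd
import pytest

from soilmulch.synthetic import ScenarioConfig, generate


def short_scenario(**overrides) -> ScenarioConfig:
    """A 5-week season at 30-min sampling: fast, three irrigations."""
    base = dict(
        start="2021-01-01",
        end="2021-02-05",
        interval="30min",
        irrigation_times=("2021-01-08 10:00", "2021-01-20 10:00", "2021-02-01 10:00"),
        seed=42,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture(scope="session")
def clean_experiment():
    """Short zero-noise season: every derived quantity is exact."""
    return generate(short_scenario(temp_noise_sd=0.0, moisture_noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_experiment():
    """Short season at the default sensor noise levels."""
    return generate(short_scenario())


def constant_records(
    temp: float = 20.0,
    moist: float = 20.0,
    days: int = 2,
    freq: str = "30min",
    depths=(5.0, 10.0, 20.0, 30.0),
    treatment: str = "bare",
) -> pd.DataFrame:
    """Flat-line sensor frame: handy for trivial-metric checks."""
    times = pd.date_range("2021-01-01", periods=days * int(pd.Timedelta("1D") / pd.Timedelta(freq)), freq=freq)
    rows = [
        {"timestamp": t, "treatment": treatment, "depth_cm": d,
         "temperature_c": temp, "moisture_pct": moist}
        for t in times for d in depths
    ]
    return pd.DataFrame(rows)
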