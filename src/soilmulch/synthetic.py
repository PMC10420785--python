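"""Virtual mulching experiment with known ground truth.

Generates the same long-format sensor stream the analysis pipeline
reads — four treatments, four depths, a whole greenhouse season —
plus per-plant and per-fruit outcome tables, with every underlying
quantity recorded as ground truth so parameter recovery can be tested
end to end.

The physics is deliberately minimal but analytically checkable:

* soil temperature follows the classical damped-harmonic solution for
  a periodic surface wave: amplitude decays as ``exp(-z/d)`` with
  damping depth ``d`` and the phase lags by ``z/d`` radians; a slow
  seasonal cosine carries the daily mean through the winter dip;
* soil moisture per depth is a bucket: each irrigation refills it
  instantaneously to a fixed fraction of field capacity, after which
  it decays exponentially toward the wilting point, faster near the
  surface;
* a mulch treatment scales the diurnal temperature amplitude
  (``temp_amplitude_factor`` ≤ 1: mulch buffers the daily swing),
  shifts the mean temperature, and scales the drydown rate
  (``drydown_factor`` < 1: mulch slows evaporative loss).

Gaussian sensor noise is added after the bounded pre-noise signal.
The default treatment set is parameterized to mimic the qualitative
ordering seen in mulching trials (bare: largest temperature range,
driest; grass: smallest range, wettest) and is illustrative, not
fitted to any measured series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .water_balance import SWC_LAYERS, LayerSpec

__all__ = [
    "TreatmentFactors",
    "ScenarioConfig",
    "GroundTruth",
    "SyntheticExperiment",
    "generate",
    "diurnal_range",
]


@dataclass(frozen=True)
class TreatmentFactors:
    """How one treatment modifies the bare-soil regime."""

    temp_amplitude_factor: float = 1.0  # in (0, 1]
    drydown_factor: float = 1.0         # > 0; < 1 = slower drying
    temp_offset_c: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.temp_amplitude_factor <= 1.0:
            raise ValueError("temp_amplitude_factor must be in (0, 1]")
        if self.drydown_factor <= 0:
            raise ValueError("drydown_factor must be > 0")


#: Illustrative default treatments: bare has the widest daily
#: temperature range and fastest drydown; grass the narrowest and
#: slowest; bran runs warmest on average.
DEFAULT_TREATMENTS: dict[str, TreatmentFactors] = {
    "bare": TreatmentFactors(1.00, 1.00, 0.0),
    "newspaper": TreatmentFactors(0.45, 0.85, -0.3),
    "bran": TreatmentFactors(0.55, 0.70, +0.5),
    "grass": TreatmentFactors(0.40, 0.65, +0.2),
}

#: Per-treatment outcome means/SDs for the plant and fruit tables
#: (g plant^-1, mm plant^-1, %, kg): typical greenhouse fruit-tomato
#: magnitudes with the newspaper treatment most productive.
DEFAULT_OUTCOMES: dict[str, dict[str, tuple[float, float]]] = {
    "bare": {"biomass": (1112, 396), "yield_": (801, 285), "water": (6.2, 2.2),
             "sugar": (9.3, 0.97), "acid": (0.87, 0.17), "firmness": (1.3, 0.51)},
    "newspaper": {"biomass": (2031, 441), "yield_": (1456, 316), "water": (8.6, 1.9),
                  "sugar": (7.6, 0.64), "acid": (0.81, 0.18), "firmness": (1.8, 0.43)},
    "bran": {"biomass": (1447, 345), "yield_": (939, 224), "water": (5.0, 1.2),
             "sugar": (7.3, 0.64), "acid": (0.71, 0.15), "firmness": (1.4, 0.34)},
    "grass": {"biomass": (1311, 576), "yield_": (890, 391), "water": (6.0, 2.7),
              "sugar": (8.4, 1.54), "acid": (0.86, 0.29), "firmness": (1.1, 0.38)},
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that defines one virtual season.

    Defaults describe a winter greenhouse season (mid October to late
    February) sampled every 10 minutes at 5/10/20/30 cm under four
    treatments, with eight spray irrigations (first 10 days in, then
    every 16 days) refilling the profile to 95% of field capacity.  Field capacity and wilting point are 36
    and 14 v/v % (silty loam); the damping depth is 10 cm and the
    surface diurnal amplitude 7 °C, which puts the bare-soil profile
    daily range near 3 °C.
    """

    start: str = "2020-10-11"
    end: str = "2021-02-24"
    interval: str = "10min"
    depths: tuple[float, ...] = (5.0, 10.0, 20.0, 30.0)
    treatments: Mapping[str, TreatmentFactors] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENTS))
    irrigation_times: tuple[str, ...] | None = None  # default: every 17 d at 10:00
    refill_fraction: float = 0.95
    field_capacity_pct: float = 36.0
    wilting_point_pct: float = 14.0
    damping_depth_cm: float = 10.0
    diurnal_amplitude_c: float = 7.0
    mean_temp_c: float = 19.0
    seasonal_amplitude_c: float = 2.0
    coldest_date: str = "2020-12-25"
    peak_hour: float = 14.0
    drydown_per_day: Mapping[float, float] = field(
        default_factory=lambda: {5.0: 0.10, 10.0: 0.06, 20.0: 0.035, 30.0: 0.02})
    temp_noise_sd: float = 0.3
    moisture_noise_sd: float = 0.2
    outcomes: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OUTCOMES.items()})
    n_plants: int = 12
    n_fruits: int = 12
    seed: int = 20201011

    def __post_init__(self) -> None:
        if self.wilting_point_pct >= self.field_capacity_pct:
            raise ValueError("wilting point must be below field capacity")
        if not 0.0 < self.refill_fraction <= 1.0:
            raise ValueError("refill_fraction must be in (0, 1]")
        for d in self.depths:
            if d not in self.drydown_per_day:
                raise ValueError(f"no drydown rate configured for depth {d} cm")

    @property
    def refill_pct(self) -> float:
        return self.refill_fraction * self.field_capacity_pct

    def schedule(self) -> pd.DatetimeIndex:
        """Irrigation onsets, snapped to the sampling grid."""
        start, end = pd.Timestamp(self.start), pd.Timestamp(self.end)
        if self.irrigation_times is None:
            # first watering once the opening refill has drawn down
            # enough to leave a clear rise; then a regular rotation
            first = start.normalize() + pd.Timedelta(days=10, hours=10)
            times = pd.date_range(first, end, freq=pd.Timedelta(days=16))
        else:
            times = pd.DatetimeIndex([pd.Timestamp(t) for t in self.irrigation_times])
        if len(times) and (times[0] < start or times[-1] > end):
            raise ValueError("irrigation schedule extends outside the season")
        grid = pd.date_range(start, end, freq=self.interval)
        snapped = grid[np.minimum(grid.searchsorted(times.to_numpy()), len(grid) - 1)]
        return pd.DatetimeIndex(snapped)


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free truth for one treatment's season.

    ``theta_before``/``theta_after`` give the per-depth moisture (v/v
    %) at the grid sample just before each irrigation onset and at the
    onset itself (the post-infiltration peak).  ``swc_per_interval``
    uses the root-zone layer scheme; its sum is ``season_total_mm``.
    """

    event_times: tuple[pd.Timestamp, ...]
    theta_before: tuple[dict[float, float], ...]
    theta_after: tuple[dict[float, float], ...]
    swc_per_interval: pd.DataFrame
    season_total_mm: float

    def to_dict(self) -> dict:
        return {
            "event_times": [str(t) for t in self.event_times],
            "theta_before": [{str(k): v for k, v in d.items()} for d in self.theta_before],
            "theta_after": [{str(k): v for k, v in d.items()} for d in self.theta_after],
            "swc_per_interval": self.swc_per_interval.to_dict(orient="records"),
            "season_total_mm": self.season_total_mm,
        }


@dataclass(frozen=True)
class SyntheticExperiment:
    sensors: pd.DataFrame
    plants: pd.DataFrame
    fruits: pd.DataFrame
    truth: dict[str, GroundTruth]
    config: ScenarioConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write sensors/plants/fruits CSVs and the truth JSON."""
        from .timeseries import write_sensor_csv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "sensors": outdir / "sensors.csv",
            "plants": outdir / "plants.csv",
            "fruits": outdir / "fruits.csv",
            "truth": outdir / "truth.json",
        }
        write_sensor_csv(self.sensors, paths["sensors"])
        self.plants.to_csv(paths["plants"], index=False)
        self.fruits.to_csv(paths["fruits"], index=False)
        with open(paths["truth"], "w") as fh:
            json.dump({t: g.to_dict() for t, g in self.truth.items()}, fh, indent=1)
        return paths


def diurnal_range(config: ScenarioConfig, treatment: str, depth_cm: float) -> float:
    """Closed-form pre-noise daily temperature range at one depth."""
    m_t = config.treatments[treatment].temp_amplitude_factor
    return 2.0 * config.diurnal_amplitude_c * m_t * np.exp(-depth_cm / config.damping_depth_cm)


def _moisture_truth(
    config: ScenarioConfig,
    factors: TreatmentFactors,
    times: pd.DatetimeIndex,
    events: pd.DatetimeIndex,
) -> np.ndarray:
    """Pre-noise moisture (v/v %), shape (n_times, n_depths).

    The season opens at the refill level (the bed is watered in at
    transplanting), then each irrigation resets the decay clock.
    """
    wp, refill = config.wilting_point_pct, config.refill_pct
    anchors = pd.DatetimeIndex([times[0]]).append(events).to_numpy()
    idx = np.searchsorted(anchors, times.to_numpy(), side="right") - 1
    dt_days = (times.to_numpy() - anchors[idx]) / np.timedelta64(1, "D")
    out = np.empty((len(times), len(config.depths)))
    for j, d in enumerate(config.depths):
        k = config.drydown_per_day[d] * factors.drydown_factor
        out[:, j] = wp + (refill - wp) * np.exp(-k * dt_days)
    return out


def _temperature_truth(
    config: ScenarioConfig, factors: TreatmentFactors, times: pd.DatetimeIndex
) -> np.ndarray:
    """Pre-noise temperature (°C), shape (n_times, n_depths)."""
    t_days = (times - pd.Timestamp(config.coldest_date)) / pd.Timedelta("1D")
    seasonal = config.mean_temp_c - config.seasonal_amplitude_c * np.cos(
        2.0 * np.pi * t_days.to_numpy() / 365.25)
    hours = times.hour + times.minute / 60.0 + times.second / 3600.0
    out = np.empty((len(times), len(config.depths)))
    for j, z in enumerate(config.depths):
        phase = 2.0 * np.pi * (hours - config.peak_hour) / 24.0 - z / config.damping_depth_cm
        amp = config.diurnal_amplitude_c * factors.temp_amplitude_factor * np.exp(
            -z / config.damping_depth_cm)
        out[:, j] = seasonal + factors.temp_offset_c + amp * np.cos(phase)
    return out


def _truth_for(
    config: ScenarioConfig,
    factors: TreatmentFactors,
    times: pd.DatetimeIndex,
    events: pd.DatetimeIndex,
    moisture: np.ndarray,
    layers: Sequence[LayerSpec] = SWC_LAYERS,
) -> GroundTruth:
    depth_ix = {d: j for j, d in enumerate(config.depths)}
    ev_idx = times.searchsorted(events.to_numpy())
    theta_after = tuple(
        {d: float(moisture[i, depth_ix[d]]) for d in config.depths} for i in ev_idx
    )
    theta_before = tuple(
        {d: float(moisture[max(i - 1, 0), depth_ix[d]]) for d in config.depths}
        for i in ev_idx
    )
    # layers whose sensors are all present in this scenario
    usable = [l for l in layers if all(d in depth_ix for d in l.sensors)]
    rows = []
    for i in range(len(events) - 1):
        for layer in usable:
            after = np.mean([theta_after[i][d] for d in layer.sensors])
            before_next = np.mean([theta_before[i + 1][d] for d in layer.sensors])
            rows.append(
                {
                    "interval": i,
                    "layer": layer.name,
                    "swc_mm": (after - before_next) / 100.0 * layer.thickness_mm,
                }
            )
    swc = pd.DataFrame(rows, columns=["interval", "layer", "swc_mm"])
    return GroundTruth(
        event_times=tuple(pd.Timestamp(t) for t in events),
        theta_before=theta_before,
        theta_after=theta_after,
        swc_per_interval=swc,
        season_total_mm=float(swc["swc_mm"].sum()) if len(swc) else 0.0,
    )


def _outcome_tables(config: ScenarioConfig, rng: np.random.Generator
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    plants, fruits = [], []
    for treatment, means in config.outcomes.items():
        def draw(key: str, n: int) -> np.ndarray:
            mean, sd = means[key]
            vals = rng.normal(mean, sd, size=n)
            return np.clip(vals, 0.05 * mean, None)  # keep outcomes physical

        p = pd.DataFrame(
            {
                "treatment": treatment,
                "plant": np.arange(1, config.n_plants + 1),
                "biomass": draw("biomass", config.n_plants),
                "yield_": draw("yield_", config.n_plants),
                "water": draw("water", config.n_plants),
            }
        )
        f = pd.DataFrame(
            {
                "treatment": treatment,
                "fruit": np.arange(1, config.n_fruits + 1),
                "sugar": draw("sugar", config.n_fruits),
                "acid": draw("acid", config.n_fruits),
                "firmness": draw("firmness", config.n_fruits),
            }
        )
        plants.append(p)
        fruits.append(f)
    return pd.concat(plants, ignore_index=True), pd.concat(fruits, ignore_index=True)


def generate(config: ScenarioConfig | None = None, seed: int | None = None
             ) -> SyntheticExperiment:
    """Run the virtual experiment.

    ``seed`` overrides the config's seed.  The same config and seed
    always produce identical output (one deterministic RNG drives the
    sensor noise and the outcome draws).
    """
    config = config or ScenarioConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    times = pd.date_range(config.start, config.end, freq=config.interval)
    events = config.schedule()

    frames = []
    truth: dict[str, GroundTruth] = {}
    for treatment, factors in config.treatments.items():
        temp = _temperature_truth(config, factors, times)
        moist = _moisture_truth(config, factors, times, events)
        truth[treatment] = _truth_for(config, factors, times, events, moist)
        if config.temp_noise_sd > 0:
            temp = temp + rng.normal(0.0, config.temp_noise_sd, size=temp.shape)
        if config.moisture_noise_sd > 0:
            moist = moist + rng.normal(0.0, config.moisture_noise_sd, size=moist.shape)
        n_t, n_d = temp.shape
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": np.repeat(times.to_numpy(), n_d),
                    "treatment": treatment,
                    "depth_cm": np.tile(np.asarray(config.depths, dtype=float), n_t),
                    "temperature_c": temp.ravel(),
                    "moisture_pct": np.clip(moist.ravel(), 0.0, 100.0),
                }
            )
        )
    sensors = pd.concat(frames, ignore_index=True)
    plants, fruits = _outcome_tables(config, rng)
    return SyntheticExperiment(sensors=sensors, plants=plants, fruits=fruits,
                               truth=truth, config=config)
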