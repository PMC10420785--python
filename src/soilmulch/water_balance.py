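"""Irrigation-interval soil water accounting.

Between two consecutive irrigations the root zone loses the water
stored at the first event's post-infiltration peak down to the
moisture just before the next event.  Summing that depletion over
layers and intervals gives the season's soil water consumption (SWC,
mm); each layer's share of an interval's depletion is the soil
moisture extraction pattern (SMEP, %).

Sensors sit at point depths while the water balance wants layer
averages, so a :class:`LayerSpec` carries both the layer geometry
(thickness in mm) and the sensor depths whose mean represents it.
Two default schemes are provided: three 100-mm layers over 0–30 cm
for SWC, and four midpoint-bounded slabs around the sensor depths
(75/75/100/50 mm) for the per-depth SMEP table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LayerSpec",
    "IrrigationEvent",
    "SWCResult",
    "SMEPResult",
    "SWC_LAYERS",
    "SMEP_LAYERS",
    "detect_irrigation_events",
    "events_from_log",
    "compute_swc",
    "compute_smep",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LayerSpec:
    """One soil layer: geometry plus the sensors that represent it."""

    name: str
    top_cm: float
    bottom_cm: float
    sensors: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.bottom_cm <= self.top_cm:
            raise ValueError(f"layer {self.name}: bottom must be below top")
        if not self.sensors:
            raise ValueError(f"layer {self.name}: needs at least one sensor depth")

    @property
    def thickness_mm(self) -> float:
        return (self.bottom_cm - self.top_cm) * 10.0


#: Root-zone accounting scheme: three contiguous 100-mm layers, each
#: represented by the mean of its two bounding sensors.
SWC_LAYERS: tuple[LayerSpec, ...] = (
    LayerSpec("0-10cm", 0.0, 10.0, (5.0, 10.0)),
    LayerSpec("10-20cm", 10.0, 20.0, (10.0, 20.0)),
    LayerSpec("20-30cm", 20.0, 30.0, (20.0, 30.0)),
)

#: Per-sensor-depth scheme for the extraction-pattern table, with
#: thicknesses from the midpoints between sensor depths.
SMEP_LAYERS: tuple[LayerSpec, ...] = (
    LayerSpec("5cm", 0.0, 7.5, (5.0,)),
    LayerSpec("10cm", 7.5, 15.0, (10.0,)),
    LayerSpec("20cm", 15.0, 25.0, (20.0,)),
    LayerSpec("30cm", 25.0, 30.0, (30.0,)),
)


@dataclass(frozen=True)
class IrrigationEvent:
    """One irrigation: onset plus bracketing per-depth moisture (v/v %).

    ``theta_before`` is the profile state at the last reading before
    the rise onset; ``theta_after`` the post-infiltration peak.  Both
    are keyed by sensor depth so any layer scheme can be applied later.
    """

    index: int
    onset: pd.Timestamp
    peak_time: pd.Timestamp
    theta_before: Mapping[float, float]
    theta_after: Mapping[float, float]


def _layer_theta(theta_by_depth: Mapping[float, float], layer: LayerSpec) -> float:
    try:
        return float(np.mean([theta_by_depth[d] for d in layer.sensors]))
    except KeyError as exc:
        raise ValueError(
            f"layer {layer.name}: no moisture for sensor depth {exc.args[0]}"
        ) from None


def detect_irrigation_events(
    records: pd.DataFrame,
    treatment: str | None = None,
    delta_pct: float = 1.5,
    window: str | pd.Timedelta = "6h",
    depths: Sequence[float] = (5.0, 10.0, 20.0, 30.0),
) -> list[IrrigationEvent]:
    """Find irrigation pulses in a moisture stream.

    An event opens at the first sample where the profile-mean moisture
    has risen by at least ``delta_pct`` (v/v points) above the last
    pre-rise reading within ``window``.  Onsets closer than ``window``
    are merged into one event.  Per event, ``theta_before`` is the
    reading just before the onset and ``theta_after`` the profile peak
    between onset and the earlier of (last merged onset + window, next
    event onset).  Returns an empty list, with a warning, when the
    stream has no qualifying rise.
    """
    if delta_pct <= 0:
        raise ValueError(f"delta_pct must be > 0, got {delta_pct}")
    window = pd.Timedelta(window)
    df = records
    if treatment is not None:
        df = df.loc[df["treatment"] == treatment]
        if df.empty:
            raise ValueError(f"no records for treatment {treatment!r}")

    depths = [float(d) for d in depths]
    wide = df.pivot_table(index="timestamp", columns="depth_cm",
                          values="moisture_pct").sort_index()
    wide = wide.loc[wide[depths].notna().all(axis=1), depths]
    times = wide.index.to_numpy()
    prof = wide.to_numpy().mean(axis=1)
    n = len(prof)

    # Onset candidates: local rise starts whose cumulative gain within
    # the window reaches delta.
    onsets: list[int] = []
    i = 1
    while i < n:
        if prof[i] > prof[i - 1]:
            j_max = np.searchsorted(times, times[i - 1] + window.to_numpy(), side="right")
            if prof[i:j_max].max() - prof[i - 1] >= delta_pct:
                onsets.append(i)
                # skip past this rise before looking for the next one
                i = int(np.argmax(prof[i:j_max])) + i + 1
                continue
        i += 1

    if not onsets:
        logger.warning("no irrigation events detected (delta=%.2f)", delta_pct)
        return []

    # Merge onsets closer than the window.
    merged: list[list[int]] = [[onsets[0]]]
    for o in onsets[1:]:
        if times[o] - times[merged[-1][-1]] <= window.to_numpy():
            merged[-1].append(o)
        else:
            merged.append([o])

    events: list[IrrigationEvent] = []
    for idx, group in enumerate(merged):
        onset = group[0]
        end_time = times[group[-1]] + window.to_numpy()
        j_end = np.searchsorted(times, end_time, side="right")
        if idx + 1 < len(merged):
            j_end = min(j_end, merged[idx + 1][0])
        peak = onset + int(np.argmax(prof[onset:j_end]))
        events.append(
            IrrigationEvent(
                index=idx,
                onset=pd.Timestamp(times[onset]),
                peak_time=pd.Timestamp(times[peak]),
                theta_before=dict(wide.iloc[onset - 1]) if onset > 0 else dict(wide.iloc[0]),
                theta_after=dict(wide.iloc[peak]),
            )
        )
    return events


def events_from_log(
    records: pd.DataFrame,
    onset_times: Sequence[pd.Timestamp],
    treatment: str | None = None,
    depths: Sequence[float] = (5.0, 10.0, 20.0, 30.0),
    peak_window: str | pd.Timedelta = "6h",
) -> list[IrrigationEvent]:
    """Build events from a known irrigation log, bypassing detection.

    ``theta_before`` is the last reading strictly before each logged
    onset; ``theta_after`` is the profile peak within ``peak_window``
    after it (capped at the next onset).
    """
    df = records
    if treatment is not None:
        df = df.loc[df["treatment"] == treatment]
    depths = [float(d) for d in depths]
    wide = df.pivot_table(index="timestamp", columns="depth_cm",
                          values="moisture_pct").sort_index()
    wide = wide.loc[wide[depths].notna().all(axis=1), depths]
    times = wide.index
    prof = wide.to_numpy().mean(axis=1)
    onset_times = sorted(pd.Timestamp(t) for t in onset_times)
    window = pd.Timedelta(peak_window)

    events = []
    for idx, t0 in enumerate(onset_times):
        i = int(times.searchsorted(t0, side="left"))
        if i >= len(times):
            raise ValueError(f"logged irrigation {t0} is after the sensor record ends")
        j_end = int(times.searchsorted(t0 + window, side="right"))
        if idx + 1 < len(onset_times):
            j_end = min(j_end, int(times.searchsorted(onset_times[idx + 1], side="left")))
        peak = i + int(np.argmax(prof[i:j_end]))
        events.append(
            IrrigationEvent(
                index=idx,
                onset=times[i],
                peak_time=times[peak],
                theta_before=dict(wide.iloc[max(i - 1, 0)]),
                theta_after=dict(wide.iloc[peak]),
            )
        )
    return events


@dataclass(frozen=True)
class SWCResult:
    """Soil water consumption between consecutive irrigations.

    ``per_interval`` has one row per (interval, layer) with the
    depletion in mm; negative values (net gain from redistribution or
    deep percolation) are kept, flagged, so totals stay additive.
    ``cumulative`` maps each interval's closing time to the running
    total.
    """

    per_interval: pd.DataFrame
    interval_totals: pd.DataFrame
    cumulative: pd.DataFrame
    season_total_mm: float


def compute_swc(
    events: Sequence[IrrigationEvent],
    layers: Sequence[LayerSpec] = SWC_LAYERS,
    transplant_date: pd.Timestamp | None = None,
) -> SWCResult:
    """Layered soil water consumption from an event sequence.

    For interval ``i`` (events i → i+1) and layer ``l``:
    ``SWC_{l,i} = (θ_IA,l,i − θ_IB,l,i+1) · h_l`` with θ as volume
    fractions and ``h_l`` the layer thickness in mm.  The season total
    is the exact sum over intervals and layers.  ``cumulative`` is
    reported against days after transplanting (DAT) when a transplant
    date is given, else against each interval's closing timestamp.
    """
    if len(events) < 2:
        raise ValueError("soil water consumption needs >= 2 irrigation events")
    rows = []
    for ev, nxt in zip(events[:-1], events[1:]):
        for layer in layers:
            theta_after = _layer_theta(ev.theta_after, layer)
            theta_before_next = _layer_theta(nxt.theta_before, layer)
            swc = (theta_after - theta_before_next) / 100.0 * layer.thickness_mm
            if theta_before_next > theta_after:
                logger.warning(
                    "interval %d layer %s: moisture gained (%.2f -> %.2f v/v%%); "
                    "negative consumption kept",
                    ev.index, layer.name, theta_after, theta_before_next,
                )
            rows.append(
                {
                    "interval": ev.index,
                    "start": ev.onset,
                    "end": nxt.onset,
                    "layer": layer.name,
                    "swc_mm": swc,
                    "negative": swc < 0,
                }
            )
    per_interval = pd.DataFrame(rows)
    interval_totals = (
        per_interval.groupby(["interval", "end"], as_index=False)["swc_mm"].sum()
    )
    cumulative = interval_totals.sort_values("interval", ignore_index=True)
    cumulative["cumulative_mm"] = cumulative["swc_mm"].cumsum()
    if transplant_date is not None:
        t0 = pd.Timestamp(transplant_date)
        cumulative["dat"] = (cumulative["end"] - t0) / pd.Timedelta("1D")
    return SWCResult(
        per_interval=per_interval,
        interval_totals=interval_totals,
        cumulative=cumulative,
        season_total_mm=float(per_interval["swc_mm"].sum()),
    )


@dataclass(frozen=True)
class SMEPResult:
    """Soil-moisture extraction pattern across layers.

    ``per_interval`` holds each interval's percentages (each row set
    sums to 100); ``table`` the across-interval mean ± SD per layer.
    """

    per_interval: pd.DataFrame
    table: pd.DataFrame
    excluded_intervals: tuple[int, ...]


def compute_smep(
    events: Sequence[IrrigationEvent],
    layers: Sequence[LayerSpec] = SMEP_LAYERS,
) -> SMEPResult:
    """Each layer's percentage share of the interval moisture depletion.

    ``SMEP_l = Δθ_l · h_l / Σ_l Δθ_l · h_l · 100`` with ``Δθ_l`` the
    interval's moisture reduction in layer ``l``.  Intervals whose
    total reduction is not positive carry no extraction signal and are
    excluded with a warning; all excluded is fatal.
    """
    if len(events) < 2:
        raise ValueError("extraction pattern needs >= 2 irrigation events")
    rows = []
    excluded: list[int] = []
    for ev, nxt in zip(events[:-1], events[1:]):
        drop_mm = {
            layer.name: (_layer_theta(ev.theta_after, layer)
                         - _layer_theta(nxt.theta_before, layer))
            / 100.0 * layer.thickness_mm
            for layer in layers
        }
        total = sum(drop_mm.values())
        if total <= 0:
            logger.warning("interval %d: non-positive total depletion (%.3f mm); "
                           "excluded from extraction pattern", ev.index, total)
            excluded.append(ev.index)
            continue
        for layer in layers:
            rows.append(
                {
                    "interval": ev.index,
                    "layer": layer.name,
                    "smep_pct": drop_mm[layer.name] / total * 100.0,
                }
            )
    if not rows:
        raise ValueError("all intervals had non-positive depletion; no extraction pattern")
    per_interval = pd.DataFrame(rows)
    order = [layer.name for layer in layers]
    table = (
        per_interval.groupby("layer")["smep_pct"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size")
        .reindex(order)
        .reset_index()
    )
    return SMEPResult(per_interval=per_interval, table=table,
                      excluded_intervals=tuple(excluded))
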