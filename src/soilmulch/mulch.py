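"""Hydrological characterization of mulching materials.

Two lab protocols are covered:

* a double-ring infiltrometer trial, reduced to per-step infiltration
  rates and the initial/steady permeability rates (IPR, SPR);
* the soak-and-drain protocol, reduced to the four water-handling
  indices of a mulch material: natural water content (NWC, %),
  maximum water retention (MWR, %), actual water retention
  (AWR, kg m^-2) and saturated water-loss rate (SWL, g kg^-1 h^-1).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "InfiltrationTrial",
    "InfiltrationResult",
    "MulchSample",
    "MulchWaterProps",
    "infiltration_rates",
    "water_props",
    "read_mulch_csv",
    "mulch_table",
]


@dataclass(frozen=True)
class InfiltrationTrial:
    """One double-ring infiltrometer run.

    Parameters
    ----------
    ring_area_cm2:
        Infiltration area of the inner ring, cm².  There is no standard
        ring size, so the area is always required.
    steps:
        Ordered ``(volume_ml, duration_s)`` pairs, one per refill step:
        the injected water volume and the time it took to infiltrate.
    """

    ring_area_cm2: float
    steps: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.ring_area_cm2 <= 0:
            raise ValueError(f"ring area must be > 0, got {self.ring_area_cm2}")
        if not self.steps:
            raise ValueError("infiltration trial needs at least one step")
        steps = tuple((float(q), float(t)) for q, t in self.steps)
        for n, (q, t) in enumerate(steps, start=1):
            if t <= 0:
                raise ValueError(f"step {n}: duration must be > 0, got {t}")
            if q < 0:
                raise ValueError(f"step {n}: volume must be >= 0, got {q}")
        object.__setattr__(self, "steps", steps)


@dataclass(frozen=True)
class InfiltrationResult:
    """Per-step rates (mm s^-1) and the derived IPR/SPR."""

    rates: tuple[float, ...]
    ipr: float
    spr: float
    plateau_start: int | None  # index into rates; None = no plateau found


def infiltration_rates(
    trial: InfiltrationTrial,
    plateau_tol: float = 0.10,
    ipr_first_step_only: bool = False,
) -> InfiltrationResult:
    """Reduce an infiltrometer trial to rates and IPR/SPR.

    The per-step rate is ``V = 10 * Q / (S * T)`` with ``Q`` in mL and
    ``S`` in cm², so that ``Q/S`` is a water depth in cm and the factor
    10 converts it to mm; ``V`` is then in mm s^-1.

    The steady plateau is found by scanning backwards from the last
    step: a step joins the plateau while its rate is within
    ``plateau_tol`` (relative) of the running plateau mean.  A plateau
    must span at least two steps.  SPR is the plateau mean; IPR is the
    mean of the pre-plateau steps (all steps when no plateau exists, or
    just the first step with ``ipr_first_step_only``).  For a trial
    whose plateau covers every step, IPR equals SPR.
    """
    s = trial.ring_area_cm2
    rates = tuple(10.0 * q / (s * t) for q, t in trial.steps)

    plateau_start: int | None = None
    if len(rates) >= 2:
        mean = rates[-1]
        count = 1
        start = len(rates) - 1
        for i in range(len(rates) - 2, -1, -1):
            r = rates[i]
            close = abs(r - mean) <= plateau_tol * mean if mean > 0 else r == 0
            if close:
                mean = (mean * count + r) / (count + 1)
                count += 1
                start = i
            else:
                break
        if count >= 2:
            plateau_start = start

    if plateau_start is None:
        spr = float("nan")
        pre = rates
    else:
        plateau = rates[plateau_start:]
        spr = sum(plateau) / len(plateau)
        pre = rates[:plateau_start]
        if not pre:  # constant-rate trial: whole series is the plateau
            pre = plateau
    ipr = pre[0] if ipr_first_step_only else sum(pre) / len(pre)
    return InfiltrationResult(rates=rates, ipr=ipr, spr=spr, plateau_start=plateau_start)


@dataclass(frozen=True)
class MulchSample:
    """Weights from the soak-and-drain protocol for one material.

    ``g_natural`` (air-dry), ``g_dry`` (oven-dry), ``g_soaked``
    (after a 24-h soak) and ``g_drained`` (after a further 24-h drain)
    are in kg; ``area_m2`` is the sample's covered area in m².
    """

    g_natural: float
    g_dry: float
    g_soaked: float
    g_drained: float
    area_m2: float

    def __post_init__(self) -> None:
        for name in ("g_natural", "g_dry", "g_soaked", "g_drained", "area_m2"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not (self.g_dry <= self.g_natural <= self.g_soaked):
            raise ValueError(
                "expected g_dry <= g_natural <= g_soaked "
                f"(got {self.g_dry}, {self.g_natural}, {self.g_soaked}); "
                "check for swapped measurements"
            )
        if self.g_drained > self.g_soaked:
            raise ValueError(
                f"drained weight {self.g_drained} exceeds soaked weight "
                f"{self.g_soaked}; check for swapped measurements"
            )


@dataclass(frozen=True)
class MulchWaterProps:
    nwc: float  # natural water content, % of dry weight
    mwr: float  # maximum water retention, % of natural weight
    awr: float  # actual water retention, kg m^-2
    swl: float  # saturated water-loss rate, g kg^-1 h^-1


def water_props(sample: MulchSample) -> MulchWaterProps:
    """Compute NWC, MWR, AWR and SWL for one mulch sample.

    NWC = (G_n - G_d) / G_d * 100
    MWR = (G_a24 - G_n) / G_n * 100
    AWR = (G_a24 - G_n) / S_m
    SWL = (G_a24 - G_l24) / G_n * 1000 / 24

    where G_n, G_d, G_a24, G_l24 are the natural, oven-dry, 24-h-soaked
    and 24-h-drained weights (kg) and S_m the sample area (m²).  The
    water-loss rate is averaged over the fixed 24-h drain window.
    """
    nwc = (sample.g_natural - sample.g_dry) / sample.g_dry * 100.0
    mwr = (sample.g_soaked - sample.g_natural) / sample.g_natural * 100.0
    awr = (sample.g_soaked - sample.g_natural) / sample.area_m2
    swl = (sample.g_soaked - sample.g_drained) / sample.g_natural * 1000.0 / 24.0
    return MulchWaterProps(nwc=nwc, mwr=mwr, awr=awr, swl=swl)


# ---------------------------------------------------------------------------
# CSV plumbing

_REQUIRED_COLS = ("material", "g_natural", "g_dry", "g_soaked", "g_drained", "area_m2")


def read_mulch_csv(path: str | Path) -> dict[str, MulchSample]:
    """Read one soak-and-drain sample per row.

    Required columns: material, g_natural, g_dry, g_soaked, g_drained,
    area_m2.  Extra columns (mass per area, thickness, ...) are ignored
    here; they are metadata for the report writer.
    """
    samples: dict[str, MulchSample] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _REQUIRED_COLS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"mulch CSV {path} is missing columns: {', '.join(missing)}")
        for row in reader:
            samples[row["material"]] = MulchSample(
                g_natural=float(row["g_natural"]),
                g_dry=float(row["g_dry"]),
                g_soaked=float(row["g_soaked"]),
                g_drained=float(row["g_drained"]),
                area_m2=float(row["area_m2"]),
            )
    return samples


def mulch_table(
    samples: dict[str, MulchSample],
    trials: dict[str, InfiltrationTrial] | None = None,
    meta: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Assemble the material-characterization report table.

    One row per material with weight/thickness metadata (if given),
    IPR/SPR (if an infiltration trial is given) and NWC/MWR/AWR/SWL.
    """
    rows = []
    for material, sample in samples.items():
        props = water_props(sample)
        row: dict[str, object] = {"material": material}
        if meta and material in meta:
            row.update(meta[material])
        if trials and material in trials:
            res = infiltration_rates(trials[material])
            row["ipr_mm_s"] = res.ipr
            row["spr_mm_s"] = res.spr
        row.update(
            nwc_pct=props.nwc,
            mwr_pct=props.mwr,
            awr_kg_m2=props.awr,
            swl_g_kg_h=props.swl,
        )
        rows.append(row)
    return pd.DataFrame(rows)
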