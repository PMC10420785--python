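"""Water-use efficiency, fruit taste index and control comparisons.

WUE_b and WUE_y are grams of biomass / yield produced per mm of water
consumed.  The taste index is ``sugar / (20 * acid) + acid`` on the
percent sugar and acid contents of the fruit juice — a palatability
score balancing sweetness against sourness.

When per-plant (or per-fruit) replicates are available there are two
estimators for a treatment-level ratio: average the per-sample ratios
(the default) or take the ratio of means.  Both are reported, since
published tables are rarely explicit about which they used and the two
can differ noticeably for skewed replicate distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlantOutcome",
    "FruitQuality",
    "WUEResult",
    "TasteResult",
    "wue",
    "taste_index",
    "percent_change",
    "wue_table",
    "quality_table",
    "percent_change_table",
]


def _check_replicates(reps: pd.DataFrame | None, cols: tuple[str, ...], what: str) -> None:
    if reps is None:
        return
    missing = [c for c in cols if c not in reps.columns]
    if missing:
        raise ValueError(f"{what} replicates missing columns: {', '.join(missing)}")


@dataclass(frozen=True)
class PlantOutcome:
    """Per-treatment plant outcomes: means, with optional replicates.

    biomass and yield are g plant^-1; water is the seasonal water
    consumption in mm plant^-1.  ``replicates``, when given, has one
    row per plant with columns biomass, yield_, water.
    """

    treatment: str
    biomass: float
    yield_: float
    water: float
    replicates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if min(self.biomass, self.yield_) < 0:
            raise ValueError("biomass and yield must be >= 0")
        _check_replicates(self.replicates, ("biomass", "yield_", "water"), "plant")


@dataclass(frozen=True)
class FruitQuality:
    """Per-treatment fruit quality: sugar %, acid %, firmness kg."""

    treatment: str
    sugar: float
    acid: float
    firmness: float | None = None
    replicates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_replicates(self.replicates, ("sugar", "acid"), "fruit")


@dataclass(frozen=True)
class WUEResult:
    wue_b: float  # g mm^-1, default estimator
    wue_y: float
    wue_b_ratio_of_means: float
    wue_y_ratio_of_means: float
    per_plant: pd.DataFrame | None = None


def wue(outcome: PlantOutcome) -> WUEResult:
    """Water-use efficiency for biomass and yield, g mm^-1.

    Without replicates both estimators coincide with mean/mean.  With
    replicates the default is the mean of per-plant ratios; the ratio
    of treatment means is reported alongside.
    """
    if outcome.water <= 0:
        raise ValueError(f"water consumption must be > 0, got {outcome.water}")
    rom_b = outcome.biomass / outcome.water
    rom_y = outcome.yield_ / outcome.water
    if outcome.replicates is None:
        return WUEResult(rom_b, rom_y, rom_b, rom_y)
    reps = outcome.replicates
    if (reps["water"] <= 0).any():
        raise ValueError("every replicate needs water consumption > 0")
    per_plant = pd.DataFrame(
        {
            "wue_b": reps["biomass"] / reps["water"],
            "wue_y": reps["yield_"] / reps["water"],
        }
    )
    rom_b = reps["biomass"].mean() / reps["water"].mean()
    rom_y = reps["yield_"].mean() / reps["water"].mean()
    return WUEResult(
        wue_b=float(per_plant["wue_b"].mean()),
        wue_y=float(per_plant["wue_y"].mean()),
        wue_b_ratio_of_means=float(rom_b),
        wue_y_ratio_of_means=float(rom_y),
        per_plant=per_plant,
    )


@dataclass(frozen=True)
class TasteResult:
    index: float  # default estimator
    index_ratio_of_means: float
    per_fruit: pd.Series | None = None


def taste_index(quality: FruitQuality) -> TasteResult:
    """Taste index ``sugar / (20 * acid) + acid`` (dimensionless)."""
    if quality.acid <= 0:
        raise ValueError(f"acid content must be > 0, got {quality.acid}")
    from_means = quality.sugar / (20.0 * quality.acid) + quality.acid
    if quality.replicates is None:
        return TasteResult(from_means, from_means)
    reps = quality.replicates
    if (reps["acid"] <= 0).any():
        raise ValueError("every replicate needs acid content > 0")
    per_fruit = reps["sugar"] / (20.0 * reps["acid"]) + reps["acid"]
    from_means = reps["sugar"].mean() / (20.0 * reps["acid"].mean()) + reps["acid"].mean()
    return TasteResult(
        index=float(per_fruit.mean()),
        index_ratio_of_means=float(from_means),
        per_fruit=per_fruit,
    )


def percent_change(value: float, reference: float) -> float:
    """Relative change versus a reference, in percent."""
    if reference <= 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    return 100.0 * (value - reference) / reference


# ---------------------------------------------------------------------------
# Treatment-table helpers over per-sample frames

def _per_treatment(df: pd.DataFrame, cols: list[str]):
    for treatment, g in df.groupby("treatment", sort=False):
        yield treatment, g[cols].reset_index(drop=True)


def wue_table(plants: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment WUE table from a per-plant frame.

    Expects columns treatment, biomass, yield_, water (one row per
    plant).  Returns means plus both WUE estimators per treatment.
    """
    rows = []
    for treatment, reps in _per_treatment(plants, ["biomass", "yield_", "water"]):
        out = PlantOutcome(
            treatment=treatment,
            biomass=float(reps["biomass"].mean()),
            yield_=float(reps["yield_"].mean()),
            water=float(reps["water"].mean()),
            replicates=reps,
        )
        res = wue(out)
        rows.append(
            {
                "treatment": treatment,
                "biomass_g": out.biomass,
                "yield_g": out.yield_,
                "water_mm": out.water,
                "wue_b": res.wue_b,
                "wue_y": res.wue_y,
                "wue_b_rom": res.wue_b_ratio_of_means,
                "wue_y_rom": res.wue_y_ratio_of_means,
            }
        )
    return pd.DataFrame(rows)


def quality_table(fruits: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment fruit-quality table from a per-fruit frame."""
    cols = ["sugar", "acid"] + (["firmness"] if "firmness" in fruits.columns else [])
    rows = []
    for treatment, reps in _per_treatment(fruits, cols):
        q = FruitQuality(
            treatment=treatment,
            sugar=float(reps["sugar"].mean()),
            acid=float(reps["acid"].mean()),
            firmness=float(reps["firmness"].mean()) if "firmness" in cols else None,
            replicates=reps,
        )
        res = taste_index(q)
        row = {
            "treatment": treatment,
            "sugar_pct": q.sugar,
            "acid_pct": q.acid,
            "taste_index": res.index,
            "taste_index_rom": res.index_ratio_of_means,
        }
        if q.firmness is not None:
            row["firmness_kg"] = q.firmness
        rows.append(row)
    return pd.DataFrame(rows)


def percent_change_table(
    table: pd.DataFrame, reference: str, columns: list[str] | None = None
) -> pd.DataFrame:
    """Percent change of each treatment versus the reference treatment.

    ``table`` is any per-treatment frame with a ``treatment`` column;
    numeric columns (or the given subset) are compared row-wise against
    the reference treatment's row.
    """
    idx = table.set_index("treatment")
    if reference not in idx.index:
        raise ValueError(f"reference treatment {reference!r} not in table")
    cols = columns or [c for c in idx.columns if pd.api.types.is_numeric_dtype(idx[c])]
    ref = idx.loc[reference, cols]
    if (ref <= 0).any():
        bad = [c for c in cols if ref[c] <= 0]
        raise ValueError(f"reference values must be > 0 (columns: {', '.join(bad)})")
    out = (idx[cols] - ref) / ref * 100.0
    return out.drop(index=reference).reset_index()
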