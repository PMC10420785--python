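"""Daily, monthly and season-long metrics from multi-depth sensor streams.

The raw input is a long-format table of timestamped soil temperature
(°C) and volumetric moisture (v/v %) readings at several depths under
each treatment.  The derived quantities follow field convention:

DMnT / DMT / DMxT
    daily minimum / mean / maximum soil temperature of the profile
    series (the across-depth mean at each timestamp);
DTR
    daily soil temperature range, DMxT - DMnT;
DMSM
    daily mean soil moisture of the profile series, v/v %.

The profile series is the unweighted mean over the sensor depths;
no weighting is implied by a statement like "over the 0-30 cm
profile", but a thickness-weighted variant is available.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "load_sensor_csv",
    "write_sensor_csv",
    "daily_summaries",
    "period_summary",
    "monthly_depth_difference",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("timestamp", "treatment", "depth_cm", "temperature_c", "moisture_pct")


def load_sensor_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    depths: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Load a long-format sensor CSV into the canonical frame.

    ``column_map`` renames file columns onto the canonical names in
    ``REQUIRED_COLUMNS``.  Rows with unparseable timestamps or
    non-numeric readings are dropped with a logged warning; a missing
    required column is fatal.  With ``depths`` given, any other depth
    value is fatal (it signals a schema mismatch, not a bad row).
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sensor CSV {path} is missing columns: {', '.join(missing)}")

    n_raw = len(df)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
    for col in ("depth_cm", "temperature_c", "moisture_pct"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = ts.isna() | df[["depth_cm", "temperature_c", "moisture_pct"]].isna().any(axis=1)
    if bad.any():
        logger.warning("%s: skipped %d of %d malformed rows", path, int(bad.sum()), n_raw)
    df = df.loc[~bad].assign(timestamp=ts[~bad])

    if depths is not None:
        unknown = sorted(set(df["depth_cm"]) - set(float(d) for d in depths))
        if unknown:
            raise ValueError(f"unknown sensor depths {unknown}; expected {list(depths)}")
    return df.sort_values(["treatment", "timestamp", "depth_cm"], ignore_index=True)


def write_sensor_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical frame back to CSV (lossless round-trip)."""
    out = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S")
    out.to_csv(path, index=False)


def _profile_series(df: pd.DataFrame, depths: Sequence[float],
                    depth_weights: Mapping[float, float] | None) -> pd.DataFrame:
    """Across-depth mean of temperature and moisture at each timestamp.

    Timestamps missing any configured depth are dropped: a profile mean
    over a partial depth set would not be comparable across time.
    """
    depths = [float(d) for d in depths]
    unknown = sorted(set(df["depth_cm"]) - set(depths))
    if unknown:
        raise ValueError(f"unknown sensor depths {unknown}; expected {depths}")
    wide_t = df.pivot_table(index=["treatment", "timestamp"], columns="depth_cm",
                            values="temperature_c")
    wide_m = df.pivot_table(index=["treatment", "timestamp"], columns="depth_cm",
                            values="moisture_pct")
    complete = wide_t[depths].notna().all(axis=1) & wide_m[depths].notna().all(axis=1)
    wide_t, wide_m = wide_t.loc[complete, depths], wide_m.loc[complete, depths]
    if depth_weights is None:
        w = np.full(len(depths), 1.0 / len(depths))
    else:
        w = np.array([depth_weights[d] for d in depths], dtype=float)
        w = w / w.sum()
    prof = pd.DataFrame(
        {
            "profile_temp": wide_t.to_numpy() @ w,
            "profile_moist": wide_m.to_numpy() @ w,
        },
        index=wide_t.index,
    )
    return pd.concat([prof, wide_t.add_prefix("temp_"), wide_m.add_prefix("moist_")], axis=1)


def daily_summaries(
    records: pd.DataFrame,
    depths: Sequence[float] = (5.0, 10.0, 20.0, 30.0),
    min_coverage: float = 0.8,
    expected_per_day: int | None = None,
    depth_weights: Mapping[float, float] | None = None,
    per_depth_range: bool = False,
) -> pd.DataFrame:
    """One row of daily metrics per (treatment, civil day).

    DMnT/DMxT are the extremes of the profile-mean temperature series
    within the day (with ``per_depth_range``, DTR is instead the mean
    of the per-depth daily ranges); DMT and DMSM are time-means.  Days
    with fewer than ``min_coverage`` of the expected samples are kept
    but flagged ``valid=False`` so period statistics can exclude them.
    The expected count per day defaults to the modal sampling interval.
    """
    prof = _profile_series(records, depths, depth_weights).reset_index()
    if prof.empty:
        raise ValueError("no complete-profile timestamps in the input")
    prof["date"] = prof["timestamp"].dt.normalize()

    if expected_per_day is None:
        dt = prof.groupby("treatment")["timestamp"].diff().dropna()
        step = dt.mode().iloc[0] if len(dt) else pd.Timedelta("10min")
        expected_per_day = max(int(pd.Timedelta("1D") / step), 1)

    depths = [float(d) for d in depths]
    agg: dict[str, tuple[str, str]] = {
        "DMnT": ("profile_temp", "min"),
        "DMT": ("profile_temp", "mean"),
        "DMxT": ("profile_temp", "max"),
        "DMSM": ("profile_moist", "mean"),
        "n_samples": ("profile_temp", "size"),
    }
    for d in depths:
        agg[f"temp_{d:g}cm"] = (f"temp_{d}", "mean")
        agg[f"moist_{d:g}cm"] = (f"moist_{d}", "mean")
    daily = prof.groupby(["treatment", "date"]).agg(**agg).reset_index()
    if per_depth_range:
        rng = (
            prof.groupby(["treatment", "date"])[[f"temp_{d}" for d in depths]]
            .agg(lambda s: s.max() - s.min())
            .mean(axis=1)
        )
        daily["DTR"] = rng.to_numpy()
    else:
        daily["DTR"] = daily["DMxT"] - daily["DMnT"]
    daily["valid"] = daily["n_samples"] >= min_coverage * expected_per_day
    return daily


_METRICS = ("DMnT", "DMT", "DMxT", "DTR", "DMSM")


def period_summary(daily: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment mean ± sample SD of each daily metric over valid days.

    Covers the profile metrics (DMnT, DMT, DMxT, DTR, DMSM) and every
    per-depth daily-mean column present.  Needs at least two valid days.
    """
    valid = daily.loc[daily["valid"]]
    if valid.empty:
        raise ValueError("no valid days: all days fell below the coverage threshold")
    counts = valid.groupby("treatment").size()
    if (counts < 2).all():
        raise ValueError("period summary needs >= 2 valid days")
    metrics = [c for c in valid.columns
               if c in _METRICS or c.startswith(("temp_", "moist_"))]
    long = valid.melt(id_vars="treatment", value_vars=metrics,
                      var_name="metric", value_name="value")
    out = (
        long.groupby(["treatment", "metric"])["value"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size")
        .reset_index()
    )
    return out


def metric_replicates(daily: pd.DataFrame, metric: str) -> dict[str, np.ndarray]:
    """Valid-day values of one metric per treatment (days as replicates).

    This is the shape the group-comparison layer consumes when letters
    are computed for sensor-derived table rows.
    """
    valid = daily.loc[daily["valid"]]
    return {t: g[metric].to_numpy() for t, g in valid.groupby("treatment")}


def monthly_depth_difference(
    daily: pd.DataFrame, depth: float, reference: str
) -> pd.DataFrame:
    """Monthly mean temperature difference (treatment − reference) at one depth.

    Valid days are grouped by calendar month; the difference of the
    monthly means of the per-depth daily mean is returned per
    (treatment, month).  Months with no valid days in either series are
    omitted with a warning.
    """
    col = f"temp_{float(depth):g}cm"
    if col not in daily.columns:
        raise ValueError(f"no per-depth column {col!r} in daily summaries")
    valid = daily.loc[daily["valid"]].copy()
    if reference not in set(valid["treatment"]):
        raise ValueError(f"reference treatment {reference!r} not present")
    valid["month"] = valid["date"].dt.to_period("M")
    monthly = valid.groupby(["treatment", "month"])[col].mean().unstack("treatment")
    ref = monthly.pop(reference)
    rows = []
    for treatment in monthly.columns:
        for month, val in monthly[treatment].items():
            if pd.isna(val) or pd.isna(ref.get(month)):
                logger.warning("month %s missing for %s or %s; omitted",
                               month, treatment, reference)
                continue
            rows.append({"treatment": treatment, "month": month,
                         "difference_c": float(val - ref[month])})
    return pd.DataFrame(rows)
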