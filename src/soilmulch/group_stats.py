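"""One-way ANOVA and Duncan's multiple range test with letter display.

Treatment tables in greenhouse experiments conventionally carry
compact letter displays: group means sharing a letter are not
significantly different under the post-hoc test.  Here the post-hoc
test is Duncan's multiple range test (MRT), whose critical range for a
stretch of ``p`` ordered means uses studentized-range quantiles at the
protection level ``1 - (1 - alpha)**(p - 1)``; the quantiles come from
:mod:`scipy.stats` rather than printed tables, so results are
reproducible to machine precision.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnovaResult", "DuncanResult", "one_way_anova", "duncan_mrt", "group_summary"]

GroupsLike = Mapping[str, Sequence[float]]


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    p_value: float
    ms_error: float
    df_error: int
    group_means: dict[str, float] = field(repr=False)
    group_sizes: dict[str, int] = field(repr=False)


def _as_arrays(groups: GroupsLike) -> dict[str, np.ndarray]:
    out = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(out) < 2:
        raise ValueError("need at least two groups")
    for label, arr in out.items():
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError(f"group {label!r} needs >= 2 replicate values")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {label!r} contains non-finite values")
    return out


def one_way_anova(groups: GroupsLike) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA decomposition.

    Returns the F statistic, its p-value, and the within-group mean
    square and degrees of freedom that the Duncan test consumes.  When
    every group has zero internal variance but the means differ, F is
    infinite and p is 0.
    """
    arrays = _as_arrays(groups)
    k = len(arrays)
    ns = {g: a.size for g, a in arrays.items()}
    n_total = sum(ns.values())
    grand = sum(a.sum() for a in arrays.values()) / n_total
    means = {g: float(a.mean()) for g, a in arrays.items()}

    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in arrays)
    ss_within = sum(float(((a - means[g]) ** 2).sum()) for g, a in arrays.items())
    df_between = k - 1
    df_error = n_total - k
    ms_between = ss_between / df_between
    ms_error = ss_within / df_error

    if ms_error == 0.0:
        f_stat = 0.0 if ms_between == 0.0 else float("inf")
        p_value = 1.0 if ms_between == 0.0 else 0.0
    else:
        f_stat = ms_between / ms_error
        p_value = float(stats.f.sf(f_stat, df_between, df_error))
    return AnovaResult(
        f_stat=float(f_stat),
        p_value=p_value,
        ms_error=float(ms_error),
        df_error=df_error,
        group_means=means,
        group_sizes=ns,
    )


@dataclass(frozen=True)
class DuncanResult:
    """Letters plus the pairwise decision matrix behind them.

    ``letters`` maps each group to its letter string, 'a' attached to
    the largest mean.  ``significant`` is a boolean DataFrame (group x
    group): True where the pair differs at the chosen level.
    """

    letters: dict[str, str]
    significant: pd.DataFrame
    means: dict[str, float]
    critical_ranges: dict[int, float]
    anova: AnovaResult


def duncan_critical_range(p: int, df_error: int, ms_error: float, n_harmonic: float,
                          alpha: float = 0.05) -> float:
    """Critical range R_p for a stretch of p ordered means.

    Uses the studentized-range quantile at Duncan's protection level
    ``1 - (1-alpha)**(p-1)`` and the harmonic-mean group size.
    """
    protection = (1.0 - alpha) ** (p - 1)
    q = stats.studentized_range.ppf(protection, p, df_error)
    return float(q * np.sqrt(ms_error / n_harmonic))


def duncan_mrt(groups: GroupsLike, alpha: float = 0.05) -> DuncanResult:
    """Duncan's multiple range test with compact letter display.

    Means are sorted in descending order.  A stretch spanning ``p``
    ranked means is non-significant when the difference of its extremes
    is at most ``R_p``; following the sequential ("protected") rule, a
    pair inside any non-significant stretch is itself non-significant.
    Letters are then the maximal non-significant stretches, so that two
    groups share a letter iff they do not differ under the test.

    Unequal group sizes are handled with the harmonic mean, the usual
    generalization for balanced-design tables.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    anova = one_way_anova(groups)
    if anova.df_error < 1:
        raise ValueError("Duncan's test needs at least 1 error degree of freedom")

    order = sorted(anova.group_means, key=anova.group_means.get, reverse=True)
    means = np.array([anova.group_means[g] for g in order])
    k = len(order)
    n_h = k / sum(1.0 / anova.group_sizes[g] for g in order)
    ranges = {
        p: duncan_critical_range(p, anova.df_error, anova.ms_error, n_h, alpha)
        for p in range(2, k + 1)
    }

    # Raw range rule on sorted indices, then closure under containment:
    # a pair inside a non-significant stretch never differs.
    raw_nonsig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        raw_nonsig[i, i] = True
        for j in range(i + 1, k):
            raw_nonsig[i, j] = raw_nonsig[j, i] = (means[i] - means[j]) <= ranges[j - i + 1]
    nonsig = raw_nonsig.copy()
    for i in range(k):
        for j in range(i + 1, k):
            if raw_nonsig[i, j]:
                nonsig[i : j + 1, i : j + 1] = True

    # Maximal non-significant stretches -> letters, top mean first.
    stretches: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        if not any(a <= i and j <= b for a, b in stretches):
            stretches.append((i, j))
    alphabet = string.ascii_lowercase
    letters = {g: "" for g in order}
    for idx, (a, b) in enumerate(stretches):
        letter = alphabet[idx % 26] * (idx // 26 + 1)
        for g in order[a : b + 1]:
            letters[g] += letter

    significant = pd.DataFrame(~nonsig, index=order, columns=order)
    return DuncanResult(
        letters=letters,
        significant=significant,
        means=dict(anova.group_means),
        critical_ranges=ranges,
        anova=anova,
    )


def group_summary(groups: GroupsLike, alpha: float = 0.05) -> pd.DataFrame:
    """Mean ± SD with Duncan letter per group, as used in report tables."""
    arrays = _as_arrays(groups)
    res = duncan_mrt(groups, alpha=alpha)
    rows = [
        {
            "group": g,
            "mean": float(a.mean()),
            "sd": float(a.std(ddof=1)),
            "n": a.size,
            "letter": res.letters[g],
            "mean_sd": f"{a.mean():.1f} ± {a.std(ddof=1):.1f} {res.letters[g]}",
        }
        for g, a in arrays.items()
    ]
    return pd.DataFrame(rows).sort_values("mean", ascending=False, ignore_index=True)
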