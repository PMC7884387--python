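"""Specimen-versus-group metric comparison via adjusted Z-scores.

An isolated specimen cannot be compared to a comparative sample with a
classical Z-score: with small n the sample mean and SD are themselves
noisy, and the classical score understates how extreme a new observation
must be to fall outside the group's variation. The adjusted Z-score
rescales the deviation by the half-width of the two-sided Student-t
prediction interval,

    z_adj = (x - X) / ( t_{1-alpha/2, n-1} * sqrt( SD^2 * (1 + 1/n) ) )

where X, SD and n are the comparative sample mean, sample standard
deviation (n-1 denominator) and size. By construction |z_adj| <= 1 if and
only if x lies inside the group's two-sided 100(1-alpha)% prediction
interval; at the default alpha = 0.05 the band [-1, +1] covers 95% of the
group's variation, whatever n is.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_core import ComparativeStats, read_comparative_stats

__all__ = [
    "adjusted_z",
    "zscore_profile",
    "crown_index",
    "crown_area",
    "SpecimenMeasurements",
    "ZScoreProfile",
    "si_optional_checks",
]


@dataclass
class SpecimenMeasurements:
    """A single specimen's variable → value map (units documented per variable)."""

    specimen_id: str
    values: dict

    def __post_init__(self):
        for k, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"measurement {k!r} is not finite")


@dataclass
class ZScoreProfile:
    """Adjusted Z-scores of one specimen against each comparative group."""

    table: pd.DataFrame  # columns: group, variable, adjusted_z
    unmatched: list = field(default_factory=list)


def adjusted_z(x: float, stats: ComparativeStats, alpha: float = 0.05) -> float:
    """Prediction-interval-scaled deviation of ``x`` from a comparative group.

    Parameters
    ----------
    x : float
        The specimen's measurement, same units as the group statistics.
    stats : ComparativeStats
        Group mean, sample SD (n-1 denominator) and size.
    alpha : float
        Two-sided tail probability; 0.05 makes |z| <= 1 the 95% band.

    Returns
    -------
    float
        Dimensionless score, sign matching ``x - mean``. A zero group SD
        with ``x != mean`` yields a signed infinity.
    """
    if not math.isfinite(x):
        raise ValueError("measurement must be finite")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    num = x - stats.mean
    if stats.sd == 0:
        return 0.0 if num == 0 else math.copysign(math.inf, num)
    t = sps.t.ppf(1 - alpha / 2, stats.n - 1)
    return num / (t * math.sqrt(stats.sd**2 * (1 + 1 / stats.n)))


def adjusted_z_vec(x, mean, sd, n, alpha: float = 0.05):
    """Vectorised :func:`adjusted_z` (no zero-SD handling); used by simulations."""
    x, mean, sd, n = map(np.asarray, (x, mean, sd, n))
    t = sps.t.ppf(1 - alpha / 2, n - 1)
    return (x - mean) / (t * np.sqrt(sd**2 * (1 + 1 / n)))


def zscore_profile(
    spec: SpecimenMeasurements,
    stats: list[ComparativeStats],
    alpha: float = 0.05,
) -> ZScoreProfile:
    """Adjusted Z-score of every specimen variable against every matching group.

    Variables without any comparative record are reported in
    ``unmatched`` rather than silently dropped.
    """
    rows = []
    matched_vars = set()
    for st in stats:
        if st.variable in spec.values:
            matched_vars.add(st.variable)
            rows.append(
                (st.group, st.variable, adjusted_z(spec.values[st.variable], st, alpha))
            )
    unmatched = sorted(set(spec.values) - matched_vars)
    if not rows:
        raise ValueError(
            "no (group, variable) pair in the comparative statistics matches "
            f"the specimen's variables {sorted(spec.values)}"
        )
    return ZScoreProfile(
        pd.DataFrame(rows, columns=["group", "variable", "adjusted_z"]),
        unmatched=unmatched,
    )


def crown_index(breadth: float, length: float) -> float:
    """Crown index in percent: breadth divided by length × 100."""
    if length <= 0:
        raise ValueError("length must be positive")
    return 100.0 * breadth / length


def crown_area(length: float, breadth: float) -> float:
    """Crown area in mm²: length × breadth."""
    if length <= 0 or breadth <= 0:
        raise ValueError("crown dimensions must be positive")
    return length * breadth


def si_optional_checks(
    spec: SpecimenMeasurements, stats_path, alpha: float = 0.05
) -> ZScoreProfile | None:
    """Optional re-check against an externally supplied comparative table.

    The comparative dental summary tables this pipeline was designed
    around are not publicly deposited; when the user has obtained them
    they can be dropped in as a standard stats CSV and the full profile is
    recomputed. Returns ``None`` when the table is absent.
    """
    if not os.path.exists(str(stats_path)):
        return None
    return zscore_profile(spec, read_comparative_stats(stats_path), alpha=alpha)
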