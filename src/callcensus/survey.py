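"""Population arithmetic: transect extrapolation and estimate comparison.

The strip-transect estimate scales the count of calling males observed in
the surveyed strip by the ratio of the whole study area to the strip:

    N = n_observed * total_area / survey_area

It is compared side by side with the acoustic-clustering estimate (number
of affinity-propagation clusters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class TransectSurvey:
    """One transect campaign: repeated strip counts plus group composition."""

    transect_lengths_km: list[float]
    strip_half_width_m: float = 150.0
    counts_per_day: list[int] = field(default_factory=list)
    survey_area_km2: float | None = None
    total_area_km2: float | None = None
    group_sizes: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.survey_area_km2 is None:
            self.survey_area_km2 = sum(
                2 * self.strip_half_width_m / 1000.0 * L
                for L in self.transect_lengths_km
            )
        if (
            self.total_area_km2 is not None
            and self.survey_area_km2 > self.total_area_km2
        ):
            warnings.warn("survey area exceeds total area")


@dataclass(frozen=True)
class PopulationEstimate:
    raw: float
    rounded: int


def estimate_population(
    n_males: int, survey_area_km2: float, total_area_km2: float
) -> PopulationEstimate:
    """Strip-transect extrapolation to the whole area.

    Linear in both the observed count and the total area; halving the
    survey area doubles the estimate.
    """
    if survey_area_km2 <= 0 or total_area_km2 <= 0:
        raise ValueError("areas must be positive")
    if n_males < 0:
        raise ValueError("n_males must be >= 0")
    raw = n_males * total_area_km2 / survey_area_km2
    return PopulationEstimate(raw=raw, rounded=int(round(raw)))


@dataclass(frozen=True)
class GroupStatistics:
    mean: float
    se: float
    minimum: int
    maximum: int
    n_groups: int
    n_individuals: int


def group_statistics(group_sizes) -> GroupStatistics:
    """Mean +/- SE and range of breeding-group sizes."""
    sizes = np.asarray(group_sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("need at least one group")
    se = float(sizes.std(ddof=1) / np.sqrt(sizes.size)) if sizes.size > 1 else 0.0
    return GroupStatistics(
        mean=float(sizes.mean()),
        se=se,
        minimum=int(sizes.min()),
        maximum=int(sizes.max()),
        n_groups=int(sizes.size),
        n_individuals=int(sizes.sum()),
    )


def max_over_repeats(counts_per_day) -> int:
    """Retain the highest daily count of a repeated transect survey."""
    counts = list(counts_per_day)
    if not counts:
        raise ValueError("need at least one day of counts")
    return max(counts)


@dataclass(frozen=True)
class EstimateComparison:
    clustering_count: float
    transect_estimate: float
    pct_vs_clustering: float  # (transect - clustering) / clustering * 100
    pct_vs_transect: float  # (clustering - transect) / transect * 100


def compare_estimates(
    clustering_count: float, transect_estimate: float
) -> EstimateComparison:
    """Relative difference of the two estimators, both conventions.

    Reported against both denominators since practice varies on which
    estimate is the reference.
    """
    if clustering_count <= 0:
        raise ValueError("clustering_count must be positive")
    return EstimateComparison(
        clustering_count=clustering_count,
        transect_estimate=transect_estimate,
        pct_vs_clustering=(transect_estimate - clustering_count)
        / clustering_count * 100.0,
        pct_vs_transect=(clustering_count - transect_estimate)
        / transect_estimate * 100.0,
    )
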