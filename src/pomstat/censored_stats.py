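"""Summary statistics of censored series under half-LOQ substitution.

Regulatory practice (Directive 2009/90/EC) replaces every left-censored
reading by half its LOQ before averaging.  When most readings sit below the
LOQ this collapses the conventional standard deviation — an all-censored
year has stdev exactly 0, suggesting a perfectly certain assessment.  The
*modified* standard deviation counters that: the mean keeps the half-LOQ
substitution, but inside the deviation sum each censored reading is set to
0, so its deviation from the half-LOQ mean is maximal rather than zero.
Both statistics use the sample (n−1) divisor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .monitoring_io import IndicatorSeries

__all__ = ["SeriesStats", "substituted_values", "zero_substituted_values",
           "stats_from_values", "series_stats"]


@dataclass(frozen=True)
class SeriesStats:
    """Mean, maximum and the two standard deviations of one series (µg/l).

    ``stdev_conventional`` / ``stdev_modified`` are ``None`` when n = 1
    (a single observation carries no spread information).
    """

    mean: float
    maximum: float
    stdev_conventional: float | None
    stdev_modified: float | None
    n: int
    n_censored: int


def substituted_values(series: IndicatorSeries) -> list[float]:
    """Half-LOQ substitution, order preserved: censored → LOQ/2."""
    return [obs.substituted() for obs in series.observations]


def zero_substituted_values(series: IndicatorSeries) -> list[float]:
    """Censored readings set to 0, quantified ones unchanged (for mod stdev)."""
    return [0.0 if obs.censored else obs.value for obs in series.observations]


def stats_from_values(
    substituted: Sequence[float],
    zero_substituted: Sequence[float],
    n_censored: int,
) -> SeriesStats:
    """Statistics from pre-substituted value lists.

    ``substituted`` feeds the mean, maximum and conventional stdev;
    ``zero_substituted`` feeds the deviation sum of the modified stdev,
    which is still taken around the half-LOQ mean.
    """
    n = len(substituted)
    if n == 0:
        raise ValueError("cannot compute statistics of an empty series")
    if len(zero_substituted) != n:
        raise ValueError("substituted and zero-substituted lengths differ")
    maximum = max(substituted)
    if maximum == min(substituted):
        # constant series (e.g. all censored at one LOQ): the mean and a zero
        # spread must hold exactly, not to within summation rounding
        mean = maximum
    else:
        mean = math.fsum(substituted) / n
    if n == 1:
        return SeriesStats(mean, maximum, None, None, 1, n_censored)
    conv = math.sqrt(math.fsum((x - mean) ** 2 for x in substituted) / (n - 1))
    mod = math.sqrt(math.fsum((x - mean) ** 2 for x in zero_substituted) / (n - 1))
    return SeriesStats(mean, maximum, conv, mod, n, n_censored)


def series_stats(series: IndicatorSeries) -> SeriesStats:
    """Summary statistics of a monitoring series under half-LOQ substitution."""
    n_censored = sum(1 for obs in series.observations if obs.censored)
    return stats_from_values(
        substituted_values(series), zero_substituted_values(series), n_censored
    )
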