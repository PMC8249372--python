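"""Chemical-status classification of indicators and water bodies.

An indicator is *good* only if its annual mean does not exceed the AA-EQS
and its maximum does not exceed the MAC-EQS ("exceeds" is strict, so a
value exactly at the threshold is still good).  Four cases partition the
outcomes:

=====  ===============  ==============
case   mean > AA-EQS    max > MAC-EQS
=====  ===============  ==============
i      no               no   (good)
ii     yes              no
iii    no               yes
iv     yes              yes
=====  ===============  ==============

The cyclodiene pesticides (aldrin, dieldrin, endrin, isodrin) are judged
against a threshold on the *sum* of their concentrations: a per-date sum
series is formed (censored member readings contribute LOQ/2 to the sum, and
0 inside the modified-stdev deviation sum) and classified like any single
indicator.

Water-body chemical status follows one-out-all-out (OOAO): a single
below-good indicator downgrades the whole water body.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .censored_stats import (
    SeriesStats,
    stats_from_values,
    substituted_values,
    zero_substituted_values,
)
from .monitoring_io import EqsStandard, IndicatorSeries

__all__ = [
    "Status",
    "Case",
    "IndicatorClass",
    "WaterBodyClass",
    "classify_indicator",
    "sum_group_values",
    "classify_sum_group",
    "classify_water_body",
]


class Status(str, Enum):
    GOOD = "good"
    BELOW_GOOD = "below_good"


class Case(str, Enum):
    I = "i"
    II = "ii"
    III = "iii"
    IV = "iv"


@dataclass(frozen=True)
class IndicatorClass:
    indicator_id: str
    status: Status
    case: Case
    mean: float
    maximum: float
    aa_eqs: float
    mac_eqs: float
    stats: SeriesStats


@dataclass(frozen=True)
class WaterBodyClass:
    water_body_id: str
    year: int
    status: Status
    indicator_classes: tuple[IndicatorClass, ...]
    decisive: frozenset[str]


def classify_indicator(
    stats: SeriesStats, eqs: EqsStandard, *, indicator_id: str | None = None
) -> IndicatorClass:
    """Assign the status class and case (i)–(iv) to one indicator."""
    mean_exceeds = stats.mean > eqs.aa_eqs
    max_exceeds = stats.maximum > eqs.mac_eqs
    if mean_exceeds and max_exceeds:
        case = Case.IV
    elif mean_exceeds:
        case = Case.II
    elif max_exceeds:
        case = Case.III
    else:
        case = Case.I
    status = Status.GOOD if case is Case.I else Status.BELOW_GOOD
    return IndicatorClass(
        indicator_id=indicator_id or eqs.indicator_id,
        status=status,
        case=case,
        mean=stats.mean,
        maximum=stats.maximum,
        aa_eqs=eqs.aa_eqs,
        mac_eqs=eqs.mac_eqs,
        stats=stats,
    )


def _aligned_member_series(
    series_list: Sequence[IndicatorSeries],
) -> list[IndicatorSeries]:
    """Align member series for per-date summation.

    If every member carries dates they are sorted onto a common date grid
    (the date sets must coincide); otherwise equal observation counts are
    required and alignment is positional.
    """
    if not series_list:
        raise ValueError("sum-group with no member series present")
    if all(s.dates is not None for s in series_list):
        date_sets = [tuple(sorted(s.dates)) for s in series_list]
        if len(set(date_sets)) != 1:
            raise ValueError(
                "sum-group members have mismatched observation dates: "
                + ", ".join(f"{s.indicator_id}={sorted(s.dates)}" for s in series_list)
            )
        aligned = []
        for s in series_list:
            order = sorted(range(s.n), key=lambda j: s.dates[j])
            aligned.append(
                IndicatorSeries(
                    s.water_body_id,
                    s.indicator_id,
                    s.year,
                    tuple(s.observations[j] for j in order),
                    dates=tuple(s.dates[j] for j in order),
                )
            )
        return aligned
    counts = {s.n for s in series_list}
    if len(counts) != 1:
        raise ValueError(
            "sum-group members have mismatched observation counts and no "
            f"dates to align on: { {s.indicator_id: s.n for s in series_list} }"
        )
    return list(series_list)


def sum_group_values(
    series_list: Sequence[IndicatorSeries],
) -> tuple[list[float], list[float], int]:
    """Per-date sums of a pesticide group.

    Returns (substituted sums, zero-substituted sums, number of dates with at
    least one censored member).  The substituted sums carry LOQ/2 for each
    censored member reading; the zero-substituted sums carry 0 for them.
    """
    aligned = _aligned_member_series(series_list)
    n = aligned[0].n
    sub = [
        sum(substituted_values(s)[j] for s in aligned) for j in range(n)
    ]
    zero = [
        sum(zero_substituted_values(s)[j] for s in aligned) for j in range(n)
    ]
    n_censored = sum(
        1
        for j in range(n)
        if any(s.observations[j].censored for s in aligned)
    )
    return sub, zero, n_censored


def classify_sum_group(
    series_list: Sequence[IndicatorSeries], eqs: EqsStandard
) -> IndicatorClass:
    """Classify a sum-group (e.g. Σ cyclodiene pesticides) like one indicator."""
    if not eqs.is_sum_group:
        raise ValueError(f"{eqs.indicator_id} is not a sum-group standard")
    stray = [s.indicator_id for s in series_list if s.indicator_id not in eqs.members]
    if stray:
        raise ValueError(f"series {stray} are not members of group {eqs.indicator_id}")
    sub, zero, n_censored = sum_group_values(series_list)
    stats = stats_from_values(sub, zero, n_censored)
    return classify_indicator(stats, eqs)


def classify_water_body(
    water_body_id: str, year: int, indicator_classes: Iterable[IndicatorClass]
) -> WaterBodyClass:
    """One-out-all-out aggregation over the classified indicators."""
    classes = tuple(indicator_classes)
    if not classes:
        raise ValueError(f"no classifiable indicators for {water_body_id}/{year}")
    decisive = frozenset(
        c.indicator_id for c in classes if c.status is Status.BELOW_GOOD
    )
    status = Status.GOOD if not decisive else Status.BELOW_GOOD
    return WaterBodyClass(water_body_id, year, status, classes, decisive)
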