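"""Four-level hierarchical aggregation of misclassification probabilities.

Level 1 is the set of classified indicators (for a below-good water body,
only the below-good ones — good indicators are not decisive there); Level 2
holds the mean- and maximum-criterion P_oms of each; Level 3 combines them
per indicator (see :func:`pomstat.misclassification.indicator_pom`); Level 4
takes the highest Level-3 value as the P_om of the water body's chemical
status.  Status P_oms are binned into the four reporting intervals
[0, 0.1], (0.1, 0.3], (0.3, 0.5] and (0.5, 1].

:func:`assess` is the whole pipeline: grouped measurement series plus an
EQS table in, per-indicator and per-water-body result tables out.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .censored_stats import series_stats, substituted_values
from .classification import (
    Status,
    WaterBodyClass,
    classify_indicator,
    classify_water_body,
    sum_group_values,
)
from .censored_stats import stats_from_values
from .misclassification import indicator_level3, select_stdev
from .monitoring_io import EqsStandard, IndicatorSeries

__all__ = [
    "BIN_LABELS",
    "bin_pom",
    "WaterBodyPom",
    "status_pom",
    "assess",
    "summarize",
    "round_sig",
    "plot_bin_summary",
]

logger = logging.getLogger(__name__)

BIN_LABELS = ("<0,0.1>", "(0.1,0.3>", "(0.3,0.5>", "(0.5,1>")
_BIN_UPPER = (0.1, 0.3, 0.5, 1.0)


def bin_pom(p: float) -> str:
    """Map a P_om to its reporting interval; the first bin is closed [0, 0.1]."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"P_om {p!r} outside [0, 1]")
    for label, upper in zip(BIN_LABELS, _BIN_UPPER):
        if p <= upper:
            return label
    return BIN_LABELS[-1]  # p == 1.0, guarded above


def round_sig(x: float, digits: int = 2) -> float:
    """Round to significant figures, as used for display in result tables."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class WaterBodyPom:
    water_body_id: str
    year: int
    status: Status
    level3: dict[str, float]
    level4: float
    decisive_indicator: str | None
    bin: str | None
    stdev_variant: str


def status_pom(
    wb: WaterBodyClass,
    level3: Mapping[str, float],
    *,
    stdev_variant: str = "modified",
) -> WaterBodyPom:
    """Level 4: the status P_om of one water body.

    For good status the maximum runs over all classified indicators; for
    below-good status only over the decisive (below-good) ones.  Indicators
    whose Level-3 value is NaN (undefined spread) are skipped; ties on the
    maximum resolve to the lexicographically smallest indicator id.
    """
    if wb.status is Status.GOOD:
        relevant = [c.indicator_id for c in wb.indicator_classes]
    else:
        relevant = sorted(wb.decisive)
    if not relevant:
        raise ValueError(f"no relevant indicators for {wb.water_body_id}/{wb.year}")
    missing = [i for i in relevant if i not in level3]
    if missing:
        raise ValueError(f"Level-3 P_om missing for indicator(s) {missing}")
    defined = [(i, level3[i]) for i in relevant if not math.isnan(level3[i])]
    if not defined:
        logger.warning(
            "all Level-3 P_oms undefined for %s/%s", wb.water_body_id, wb.year
        )
        return WaterBodyPom(
            wb.water_body_id, wb.year, wb.status, dict(level3),
            float("nan"), None, None, stdev_variant,
        )
    level4 = max(p for _, p in defined)
    decisive = min(i for i, p in defined if p == level4)
    return WaterBodyPom(
        wb.water_body_id, wb.year, wb.status, dict(level3),
        level4, decisive, bin_pom(level4), stdev_variant,
    )


def _split_standards(
    eqs_list: Sequence[EqsStandard],
) -> tuple[dict[str, EqsStandard], list[EqsStandard]]:
    individual: dict[str, EqsStandard] = {}
    groups: list[EqsStandard] = []
    for eqs in eqs_list:
        if eqs.is_sum_group:
            groups.append(eqs)
        else:
            if eqs.indicator_id in individual:
                raise ValueError(f"duplicate EQS for {eqs.indicator_id}")
            individual[eqs.indicator_id] = eqs
    return individual, groups


def assess(
    series_list: Sequence[IndicatorSeries],
    eqs_list: Sequence[EqsStandard],
    *,
    stdev_variants: Sequence[str] = ("modified",),
    gumbel_fit: str = "moments",
    truncate_support: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run classification and the full P_om hierarchy.

    Returns ``(water_body_frame, indicator_frame)``.  The water-body frame
    has one row per (water body, year, stdev variant) with the status, the
    Level-4 P_om, its bin and the decisive indicator; the indicator frame
    has one row per (water body, year, indicator, variant) with the summary
    statistics, case and criterion/Level-3 P_oms.
    """
    individual, groups = _split_standards(eqs_list)
    by_wb_year: dict[tuple[str, int], list[IndicatorSeries]] = {}
    for s in series_list:
        by_wb_year.setdefault((s.water_body_id, s.year), []).append(s)

    wb_rows: list[dict] = []
    ind_rows: list[dict] = []
    skipped: set[str] = set()
    for (wb_id, year), group_series in sorted(by_wb_year.items()):
        by_ind = {s.indicator_id: s for s in group_series}
        assessed: list[tuple] = []  # (IndicatorClass, substituted values)
        member_ids = {m for g in groups for m in g.members}
        for ind_id, s in sorted(by_ind.items()):
            if ind_id in individual:
                assessed.append(
                    (classify_indicator(series_stats(s), individual[ind_id],
                                        indicator_id=ind_id),
                     substituted_values(s))
                )
            elif ind_id not in member_ids:
                if ind_id not in skipped:
                    logger.warning("no EQS for indicator %r; not assessed", ind_id)
                    skipped.add(ind_id)
        for g in groups:
            present = [by_ind[m] for m in g.members if m in by_ind]
            if not present:
                continue
            sub, zero, n_cens = sum_group_values(present)
            stats = stats_from_values(sub, zero, n_cens)
            assessed.append((classify_indicator(stats, g), sub))
        if not assessed:
            logger.warning("no classifiable indicators for %s/%s", wb_id, year)
            continue
        wb_class = classify_water_body(wb_id, year, [c for c, _ in assessed])

        for variant in stdev_variants:
            level3: dict[str, float] = {}
            for cls, values in assessed:
                res = indicator_level3(
                    cls, values,
                    stdev_variant=variant,
                    gumbel_fit=gumbel_fit,
                    truncate_support=truncate_support,
                )
                if res is None:
                    pm = px = None
                    l3 = float("nan")
                else:
                    pm, px, l3 = res
                level3[cls.indicator_id] = l3
                ind_rows.append(
                    {
                        "wb_id": wb_id,
                        "year": year,
                        "indicator": cls.indicator_id,
                        "stdev_variant": variant,
                        "status": cls.status.value,
                        "case": cls.case.value,
                        "n": cls.stats.n,
                        "n_censored": cls.stats.n_censored,
                        "mean": cls.mean,
                        "maximum": cls.maximum,
                        "aa_eqs": cls.aa_eqs,
                        "mac_eqs": cls.mac_eqs,
                        "stdev": select_stdev(cls.stats, variant),
                        "pom_mean": pm.p_om if pm else float("nan"),
                        "pom_max": px.p_om if px else float("nan"),
                        "pom_level3": l3,
                        "bin_level3": bin_pom(l3) if not math.isnan(l3) else None,
                    }
                )
            wbp = status_pom(wb_class, level3, stdev_variant=variant)
            wb_rows.append(
                {
                    "wb_id": wb_id,
                    "year": year,
                    "stdev_variant": variant,
                    "status": wbp.status.value,
                    "n_indicators": len(assessed),
                    "below_good_indicators": ";".join(sorted(wb_class.decisive)),
                    "decisive_indicator": wbp.decisive_indicator,
                    "pom_level4": wbp.level4,
                    "bin": wbp.bin,
                }
            )

    wb_cols = ["wb_id", "year", "stdev_variant", "status", "n_indicators",
               "below_good_indicators", "decisive_indicator", "pom_level4", "bin"]
    ind_cols = ["wb_id", "year", "indicator", "stdev_variant", "status", "case",
                "n", "n_censored", "mean", "maximum", "aa_eqs", "mac_eqs",
                "stdev", "pom_mean", "pom_max", "pom_level3", "bin_level3"]
    return (
        pd.DataFrame(wb_rows, columns=wb_cols),
        pd.DataFrame(ind_rows, columns=ind_cols),
    )


def summarize(
    results: pd.DataFrame,
    by: Sequence[str] = ("stdev_variant", "status"),
    *,
    bin_column: str = "bin",
) -> pd.DataFrame:
    """Counts and percentages per P_om interval, per grouping.

    Works on either the water-body frame (``bin``) or the indicator frame
    (``bin_column="bin_level3"``).  Rows with an undefined bin are dropped.
    Percentages within each grouping sum to 100.
    """
    if results.empty:
        raise ValueError("no results to summarize")
    frame = results.dropna(subset=[bin_column]).copy()
    frame["bin"] = pd.Categorical(frame[bin_column], categories=BIN_LABELS)
    by = list(by)
    counts = (
        frame.groupby(by + ["bin"], observed=False)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby(by, observed=False)["count"].transform("sum")
    counts["pct"] = 100.0 * counts["count"] / totals.where(totals > 0)
    counts = counts[totals > 0].reset_index(drop=True)
    return counts


def plot_bin_summary(summary: pd.DataFrame, path, by: Sequence[str] | None = None):
    """Stacked-bar chart of bin percentages per grouping, written to file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if by is None:
        by = [c for c in summary.columns if c not in ("bin", "count", "pct")]
    wide = summary.pivot_table(
        index=list(by), columns="bin", values="pct", fill_value=0.0, observed=False
    ).reindex(columns=list(BIN_LABELS), fill_value=0.0)
    ax = wide.plot(kind="bar", stacked=True, colormap="viridis", figsize=(8, 5))
    ax.set_ylabel("% of assessments")
    ax.set_xlabel(" / ".join(by))
    ax.legend(title="P$_{om}$ interval", bbox_to_anchor=(1.02, 1), loc="upper left")
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
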