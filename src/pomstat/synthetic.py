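"""Synthetic monitoring data with known truth, for validation end to end.

No national monitoring database is public, so validation runs on generated
series that mimic the monitoring design: per water body, indicator and
year, ``n_per_year`` concentration draws (default 12, the monthly sampling
the legislation prescribes) from a lognormal — the standard positive-support
model for pollutant concentrations, which show strong right-skewed
variability.  Draws below the indicator's LOQ are emitted as censored
tokens ``"<loq"``.  A truth table records each indicator's true
(distributional) mean and the true class it implies against the AA-EQS, so
calibration of the computed misclassification probabilities is measurable
without re-deriving truth.

Deliberately not modelled: seasonality, temporal autocorrelation and
correlation between indicators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd
import yaml

from .classification import Status
from .hierarchy import BIN_LABELS, assess
from .monitoring_io import eqs_from_frame, series_from_frame

__all__ = [
    "IndicatorModel",
    "SyntheticConfig",
    "generate",
    "write_dataset",
    "config_from_yaml",
    "RecoveryReport",
    "recovery_experiment",
]


@dataclass(frozen=True)
class IndicatorModel:
    """True concentration model of one indicator (all values µg/l).

    ``log_mean``/``log_sd`` parameterize the underlying normal of the
    lognormal; ``log_sd = 0`` gives a degenerate constant concentration
    ``exp(log_mean)`` for edge-case testing.
    """

    indicator_id: str
    log_mean: float
    log_sd: float
    loq: float
    aa_eqs: float
    mac_eqs: float

    def __post_init__(self) -> None:
        if self.log_sd < 0:
            raise ValueError("log_sd must be non-negative")
        if self.loq <= 0:
            raise ValueError("loq must be positive")

    @property
    def true_mean(self) -> float:
        """Arithmetic mean of the lognormal: exp(log_mean + log_sd²/2)."""
        return math.exp(self.log_mean + self.log_sd**2 / 2.0)

    @property
    def censoring_probability(self) -> float:
        """P(draw < LOQ) under the true model."""
        if self.log_sd == 0.0:
            return 1.0 if math.exp(self.log_mean) < self.loq else 0.0
        z = (math.log(self.loq) - self.log_mean) / self.log_sd
        return float(0.5 * math.erfc(-z / math.sqrt(2.0)))


@dataclass(frozen=True)
class SyntheticConfig:
    indicators: tuple[IndicatorModel, ...]
    n_water_bodies: int = 20
    n_per_year: int = 12  # monthly sampling
    years: tuple[int, ...] = (2017,)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "indicators", tuple(self.indicators))
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        if self.n_water_bodies < 1 or self.n_per_year < 1 or not self.years:
            raise ValueError("need at least one water body, draw and year")


def _dates(year: int, n: int) -> list[str]:
    # spread through the year; monthly when n = 12
    return [f"{year}-{(j % 12) + 1:02d}-{15 + j // 12:02d}" for j in range(n)]


def generate(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a full synthetic dataset.

    Returns ``(measurements, eqs, truth)`` data frames in the package's CSV
    schemas.  The seed fixes the output exactly; water bodies are
    independent.
    """
    rng = np.random.default_rng(config.seed)
    meas_rows: list[dict] = []
    truth_rows: list[dict] = []
    for w in range(config.n_water_bodies):
        wb_id = f"WB{w:05d}"
        for year in config.years:
            dates = _dates(year, config.n_per_year)
            for model in config.indicators:
                if model.log_sd == 0.0:
                    draws = np.full(config.n_per_year, math.exp(model.log_mean))
                else:
                    draws = rng.lognormal(
                        model.log_mean, model.log_sd, size=config.n_per_year
                    )
                for date, x in zip(dates, draws):
                    token = f"<{model.loq!r}" if x < model.loq else repr(float(x))
                    meas_rows.append(
                        {
                            "wb_id": wb_id,
                            "indicator": model.indicator_id,
                            "year": year,
                            "date": date,
                            "value": token,
                        }
                    )
                exceeds = model.true_mean > model.aa_eqs
                truth_rows.append(
                    {
                        "wb_id": wb_id,
                        "indicator": model.indicator_id,
                        "year": year,
                        "true_mean": model.true_mean,
                        "censoring_probability": model.censoring_probability,
                        "true_exceeds_aa": exceeds,
                        "true_status": (
                            Status.BELOW_GOOD if exceeds else Status.GOOD
                        ).value,
                    }
                )
    measurements = pd.DataFrame(
        meas_rows, columns=["wb_id", "indicator", "year", "date", "value"]
    )
    eqs = pd.DataFrame(
        [
            {
                "indicator": m.indicator_id,
                "aa_eqs": m.aa_eqs,
                "mac_eqs": m.mac_eqs,
                "sum_group": "",
            }
            for m in config.indicators
        ]
    )
    truth = pd.DataFrame(truth_rows)
    return measurements, eqs, truth


def write_dataset(config: SyntheticConfig, out_dir) -> dict[str, str]:
    """Generate and write measurements.csv, eqs.csv and truth.csv."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    measurements, eqs, truth = generate(config)
    paths = {}
    for name, frame in (
        ("measurements", measurements),
        ("eqs", eqs),
        ("truth", truth),
    ):
        path = os.path.join(out_dir, f"{name}.csv")
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def config_from_yaml(path) -> SyntheticConfig:
    """Load a simulation config.

    Expected shape::

        seed: 1
        n_water_bodies: 50
        n_per_year: 12
        years: [2017]
        indicators:
          - indicator_id: benzo(a)pyrene
            log_mean: -9.2
            log_sd: 0.8
            loq: 5.0e-5
            aa_eqs: 1.7e-4
            mac_eqs: 0.27
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    indicators = tuple(IndicatorModel(**spec) for spec in raw.pop("indicators"))
    return SyntheticConfig(indicators=indicators, **raw)


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of running the pipeline against known synthetic truth."""

    details: pd.DataFrame      # per (wb, indicator, year): P_om, assessed vs true
    calibration: pd.DataFrame  # per P_om bin: n, errors, empirical error rate
    overall_error: float       # fraction of indicator assessments that are wrong


def recovery_experiment(
    config: SyntheticConfig,
    *,
    stdev_variant: str = "modified",
    gumbel_fit: str = "moments",
    truncate_support: bool = False,
) -> RecoveryReport:
    """Generate data, run the full pipeline, and compare with the truth.

    The empirical misclassification frequency within each P_om bin is the
    calibration check: a well-calibrated P_om means the error frequency
    tracks the stated probability, rising across the bins.
    """
    measurements, eqs, truth = generate(config)
    series = series_from_frame(measurements)
    standards = eqs_from_frame(eqs)
    _, indicator_frame = assess(
        series,
        standards,
        stdev_variants=(stdev_variant,),
        gumbel_fit=gumbel_fit,
        truncate_support=truncate_support,
    )
    details = indicator_frame.merge(
        truth, on=["wb_id", "indicator", "year"], validate="one_to_one"
    )
    details["error"] = details["status"] != details["true_status"]

    binned = details.dropna(subset=["bin_level3"]).copy()
    binned["bin"] = pd.Categorical(binned["bin_level3"], categories=BIN_LABELS)
    calibration = (
        binned.groupby("bin", observed=False)
        .agg(
            n=("error", "size"),
            n_errors=("error", "sum"),
            mean_pom=("pom_level3", "mean"),
        )
        .reset_index()
    )
    calibration["error_rate"] = calibration["n_errors"] / calibration["n"].where(
        calibration["n"] > 0
    )
    overall = float(details["error"].mean())
    return RecoveryReport(details, calibration, overall)
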