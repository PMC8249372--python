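"""Domain types and delimited-text I/O for water-quality monitoring data.

Concentrations are micrograms per litre (µg/l) throughout and are never
converted.  A reading below the laboratory limit of quantification (LOQ)
appears in monitoring exports as a left-censored token such as ``"< 0.001"``;
it is carried as an :class:`Observation` whose ``value`` is the LOQ itself.

The measurement file is long format — one row per observation — with columns
``wb_id, indicator, year, date (optional ISO-8601), value``.  The
environmental-quality-standards file has columns ``indicator, aa_eqs,
mac_eqs, sum_group (optional)``; a row whose ``indicator`` equals its
``sum_group`` label declares a sum-group (e.g. the cyclodiene pesticides
aldrin/dieldrin/endrin/isodrin, regulated through the sum of their
concentrations) and carries the group thresholds, while member rows carry
the label in ``sum_group`` and may leave their own thresholds blank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "MonitoringIOError",
    "Observation",
    "IndicatorSeries",
    "EqsStandard",
    "parse_observation",
    "format_observation",
    "read_measurements",
    "write_measurements",
    "series_from_frame",
    "measurements_frame",
    "read_eqs",
    "eqs_from_frame",
]

ACCEPTED_UNITS = frozenset({"µg/l", "ug/l"})


class MonitoringIOError(ValueError):
    """Malformed monitoring or standards input."""


@dataclass(frozen=True)
class Observation:
    """One concentration reading in µg/l.

    ``censored`` marks a left-censored reading; ``value`` is then the LOQ,
    otherwise the measured concentration.
    """

    value: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise MonitoringIOError(f"non-finite concentration {self.value!r}")
        if self.censored and self.value <= 0:
            raise MonitoringIOError(
                f"censored observation needs a positive LOQ, got {self.value!r}"
            )
        if not self.censored and self.value < 0:
            raise MonitoringIOError(f"negative concentration {self.value!r}")

    @classmethod
    def quantified(cls, value: float) -> "Observation":
        return cls(float(value), censored=False)

    @classmethod
    def below_loq(cls, loq: float) -> "Observation":
        return cls(float(loq), censored=True)

    def substituted(self) -> float:
        """Half-LOQ substitution: LOQ/2 if censored, else the value."""
        return self.value / 2.0 if self.censored else self.value


@dataclass(frozen=True)
class IndicatorSeries:
    """All observations of one chemical indicator in one water body and year."""

    water_body_id: str
    indicator_id: str
    year: int
    observations: tuple[Observation, ...]
    dates: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        if self.dates is not None:
            object.__setattr__(self, "dates", tuple(self.dates))
        if len(self.observations) < 1:
            raise MonitoringIOError(
                f"empty series for {self.water_body_id}/{self.indicator_id}/{self.year}"
            )
        if self.dates is not None and len(self.dates) != len(self.observations):
            raise MonitoringIOError("dates and observations differ in length")

    @property
    def n(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class EqsStandard:
    """AA-EQS / MAC-EQS thresholds (µg/l) for one indicator or sum-group."""

    indicator_id: str
    aa_eqs: float
    mac_eqs: float
    is_sum_group: bool = False
    members: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not (self.aa_eqs > 0 and math.isfinite(self.aa_eqs)):
            raise MonitoringIOError(
                f"{self.indicator_id}: AA-EQS must be positive, got {self.aa_eqs!r}"
            )
        if not (self.mac_eqs > 0 and math.isfinite(self.mac_eqs)):
            raise MonitoringIOError(
                f"{self.indicator_id}: MAC-EQS must be positive, got {self.mac_eqs!r}"
            )
        if self.mac_eqs < self.aa_eqs:
            raise MonitoringIOError(
                f"{self.indicator_id}: MAC-EQS {self.mac_eqs} < AA-EQS {self.aa_eqs}"
            )
        if self.is_sum_group and len(self.members) < 2:
            raise MonitoringIOError(
                f"sum-group {self.indicator_id} needs at least two members"
            )
        if not self.is_sum_group and self.members:
            raise MonitoringIOError(
                f"{self.indicator_id}: members given but not a sum-group"
            )


def parse_observation(token: str, *, where: str = "") -> Observation:
    """Parse a concentration token: ``"0.003"`` or left-censored ``"< 0.001"``.

    Decimal point only; a decimal comma is rejected so parsing cannot depend
    on locale.
    """
    ctx = f" at {where}" if where else ""
    text = token.strip() if isinstance(token, str) else ""
    if not text:
        raise MonitoringIOError(f"empty concentration token{ctx}")
    censored = text.startswith("<")
    number = text[1:].strip() if censored else text
    if "," in number:
        raise MonitoringIOError(
            f"decimal comma in {token!r}{ctx}; use a decimal point"
        )
    try:
        value = float(number)
    except ValueError:
        raise MonitoringIOError(f"cannot parse concentration {token!r}{ctx}") from None
    if not math.isfinite(value):
        raise MonitoringIOError(f"non-finite concentration {token!r}{ctx}")
    if censored and value <= 0:
        raise MonitoringIOError(f"censored token {token!r}{ctx} has non-positive LOQ")
    if value < 0:
        raise MonitoringIOError(f"negative concentration {token!r}{ctx}")
    return Observation(value, censored=censored)


def format_observation(obs: Observation) -> str:
    """Render an observation as its file token at full precision."""
    return f"<{obs.value!r}" if obs.censored else repr(obs.value)


_MEASUREMENT_COLUMNS = ("wb_id", "indicator", "year", "value")


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def series_from_frame(frame: pd.DataFrame) -> list[IndicatorSeries]:
    """Group long-format measurement rows into :class:`IndicatorSeries`.

    Row order within a group is preserved as observation order.  Duplicate
    (wb, indicator, year, date) rows are rejected when dates are present.
    """
    if frame.empty:
        return []
    missing = [c for c in _MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise MonitoringIOError(f"missing mandatory column(s): {', '.join(missing)}")
    has_date = "date" in frame.columns
    if "unit" in frame.columns:
        bad = sorted(set(frame["unit"].str.strip()) - ACCEPTED_UNITS - {""})
        if bad:
            raise MonitoringIOError(
                f"unsupported unit(s) {bad}; concentrations must be in µg/l"
            )
    if has_date:
        keys = frame[["wb_id", "indicator", "year", "date"]]
        dup = keys[keys["date"].str.len() > 0].duplicated(keep=False)
        if dup.any():
            offenders = keys[dup].drop_duplicates().to_dict("records")
            raise MonitoringIOError(f"duplicate (wb, indicator, year, date) rows: {offenders}")

    grouped: dict[tuple[str, str, int], dict] = {}
    for i, row in enumerate(frame.itertuples(index=False)):
        where = f"row {i + 2}"  # 1-based with header line
        try:
            year = int(str(getattr(row, "year")).strip())
        except ValueError:
            raise MonitoringIOError(
                f"non-integer year {getattr(row, 'year')!r} at {where}"
            ) from None
        key = (str(row.wb_id), str(row.indicator), year)
        obs = parse_observation(str(row.value), where=f"{where}, column 'value'")
        slot = grouped.setdefault(key, {"obs": [], "dates": []})
        slot["obs"].append(obs)
        slot["dates"].append(str(getattr(row, "date", "")) if has_date else "")

    out = []
    for (wb, ind, year), slot in grouped.items():
        dates = tuple(slot["dates"]) if has_date and all(slot["dates"]) else None
        out.append(IndicatorSeries(wb, ind, year, tuple(slot["obs"]), dates=dates))
    return out


def read_measurements(path) -> list[IndicatorSeries]:
    """Read a long-format measurements CSV into grouped series."""
    return series_from_frame(_read_table(path))


def measurements_frame(series_list: Iterable[IndicatorSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for j, obs in enumerate(s.observations):
            rows.append(
                {
                    "wb_id": s.water_body_id,
                    "indicator": s.indicator_id,
                    "year": s.year,
                    "date": s.dates[j] if s.dates else "",
                    "value": format_observation(obs),
                }
            )
    return pd.DataFrame(rows, columns=["wb_id", "indicator", "year", "date", "value"])


def write_measurements(series_list: Iterable[IndicatorSeries], path) -> None:
    """Write series back to the long CSV format, tokens at full precision."""
    measurements_frame(series_list).to_csv(path, index=False)


def _parse_threshold(text: str, *, indicator: str, name: str) -> float:
    text = text.strip()
    if not text:
        raise MonitoringIOError(f"{indicator}: missing {name}")
    try:
        value = float(text)
    except ValueError:
        raise MonitoringIOError(f"{indicator}: cannot parse {name} {text!r}") from None
    return value


def eqs_from_frame(frame: pd.DataFrame) -> list[EqsStandard]:
    if frame.empty:
        return []
    for col in ("indicator", "aa_eqs", "mac_eqs"):
        if col not in frame.columns:
            raise MonitoringIOError(f"EQS table missing column {col!r}")
    has_group = "sum_group" in frame.columns

    standards: list[EqsStandard] = []
    group_rows: dict[str, dict] = {}
    members: dict[str, list[str]] = {}
    for row in frame.itertuples(index=False):
        indicator = str(row.indicator).strip()
        label = str(getattr(row, "sum_group", "")).strip() if has_group else ""
        if label and indicator == label:
            group_rows[label] = {
                "aa": _parse_threshold(str(row.aa_eqs), indicator=label, name="AA-EQS"),
                "mac": _parse_threshold(str(row.mac_eqs), indicator=label, name="MAC-EQS"),
            }
            continue
        if label:
            members.setdefault(label, []).append(indicator)
        aa_text = str(row.aa_eqs).strip()
        mac_text = str(row.mac_eqs).strip()
        if label and not aa_text and not mac_text:
            continue  # member regulated through the sum only
        standards.append(
            EqsStandard(
                indicator,
                _parse_threshold(aa_text, indicator=indicator, name="AA-EQS"),
                _parse_threshold(mac_text, indicator=indicator, name="MAC-EQS"),
            )
        )
    for label, ids in members.items():
        if label not in group_rows:
            raise MonitoringIOError(
                f"sum-group {label!r} has member rows but no thresholds row"
            )
        g = group_rows[label]
        standards.append(
            EqsStandard(label, g["aa"], g["mac"], is_sum_group=True, members=tuple(ids))
        )
    orphan = set(group_rows) - set(members)
    if orphan:
        raise MonitoringIOError(f"sum-group(s) without members: {sorted(orphan)}")
    return standards


def read_eqs(path) -> list[EqsStandard]:
    """Read the environmental-quality-standards CSV."""
    return eqs_from_frame(_read_table(path))
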