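"""Monitoring records and censored summary statistics.

Raw-water monitoring data arrive as one row per grab sample: station, date,
parameter, measured value, and whether the laboratory detected the analyte.
Samples below the detection limit (non-detects, "censored" values) carry the
limit instead of a concentration. Summaries feed the hazard-quotient screen,
so the censoring policy — what a non-detect contributes to the mean — is an
explicit, named choice:

``detected_only``
    drop non-detects from the statistics (default; reported ranges in the
    TSWA screening tables start at detected minima, which only this policy
    reproduces);
``substitute_zero`` / ``substitute_half_dl`` / ``substitute_dl``
    replace each non-detect with 0, DL/2 or DL — the standard textbook
    substitutions for left-censored environmental data.

``n`` always counts all samples and ``n_detected`` the detected subset,
whatever the policy.
"""

from __future__ import annotations

import csv
import datetime as _dt
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .standards import _ALIAS_LOOKUP, _squash, normalize_parameter

__all__ = [
    "MonitoringRecord",
    "SummaryStats",
    "CensoringPolicy",
    "MonitoringParseError",
    "read_monitoring_csv",
    "write_monitoring_csv",
    "summarize",
    "summaries_to_frame",
]


class MonitoringParseError(ValueError):
    """A monitoring CSV row could not be parsed; message carries the line number."""


class CensoringPolicy(str, Enum):
    DETECTED_ONLY = "detected_only"
    SUBSTITUTE_ZERO = "substitute_zero"
    SUBSTITUTE_HALF_DL = "substitute_half_dl"
    SUBSTITUTE_DL = "substitute_dl"


@dataclass(frozen=True)
class MonitoringRecord:
    station: str
    date: _dt.date
    parameter: str
    value: float | None
    detected: bool
    detection_limit: float | None = None

    def __post_init__(self) -> None:
        if self.detected:
            if self.value is None:
                raise ValueError("detected record must carry a value")
            if self.value < 0 and normalize_parameter(self.parameter) != "pH":
                raise ValueError(f"negative concentration {self.value}")
        else:
            if self.detection_limit is None:
                raise ValueError("non-detect record must carry a detection limit")
            if self.value is not None and self.value > self.detection_limit:
                raise ValueError(
                    "non-detect value exceeds its detection limit "
                    f"({self.value} > {self.detection_limit})"
                )


@dataclass(frozen=True)
class SummaryStats:
    """Per station x parameter summary under a stated censoring policy."""

    station: str
    parameter: str
    n: int
    n_detected: int
    mean: float | None
    minimum: float | None
    maximum: float | None
    policy: CensoringPolicy

    @property
    def no_data(self) -> bool:
        """True when the policy left no usable values (e.g. all censored)."""
        return self.mean is None


_REQUIRED_COLUMNS = ("station", "date", "parameter", "value")


def read_monitoring_csv(
    path: str | Path,
    date_format: str | None = None,
) -> list[MonitoringRecord]:
    """Read monitoring records from CSV.

    Expected columns: ``station, date, parameter, value, detected,
    detection_limit`` (the last two optional). Non-detects are recognised
    from ``detected`` = 0/false, or from a ``<DL`` marker in the value
    column (e.g. ``<0.01``). Dates are ISO-8601 unless ``date_format``
    (a ``strptime`` pattern) overrides. Parameters outside the built-in
    alias table produce a warning but the record is kept.
    """
    records: list[MonitoringRecord] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return records
        fields = [f.strip().lower() for f in reader.fieldnames]
        missing = [c for c in _REQUIRED_COLUMNS if c not in fields]
        if missing:
            raise MonitoringParseError(f"missing required columns: {missing}")
        for lineno, row in enumerate(reader, start=2):
            row = {k.strip().lower(): (v or "").strip() for k, v in row.items() if k}
            try:
                records.append(_parse_row(row, date_format))
            except (ValueError, KeyError) as exc:
                raise MonitoringParseError(f"line {lineno}: {exc}") from exc
    return records


def _parse_row(row: dict[str, str], date_format: str | None) -> MonitoringRecord:
    raw_date = row["date"]
    if date_format:
        date = _dt.datetime.strptime(raw_date, date_format).date()
    else:
        date = _dt.date.fromisoformat(raw_date)

    parameter = row["parameter"]
    if _squash(parameter) not in _ALIAS_LOOKUP:
        warnings.warn(
            f"unknown parameter {parameter!r}; record kept without a standard",
            stacklevel=4,
        )

    raw_value = row.get("value", "")
    raw_detected = row.get("detected", "")
    raw_dl = row.get("detection_limit", "")
    dl = float(raw_dl) if raw_dl else None

    if raw_value.startswith("<"):
        # "<0.01" style censoring marker: the number is the detection limit
        dl = float(raw_value[1:])
        value, detected = None, False
    else:
        value = float(raw_value) if raw_value else None
        detected = _parse_bool(raw_detected) if raw_detected else value is not None

    return MonitoringRecord(
        station=row["station"],
        date=date,
        parameter=parameter,
        value=value,
        detected=detected,
        detection_limit=dl,
    )


def _parse_bool(text: str) -> bool:
    lowered = text.lower()
    if lowered in ("1", "true", "t", "yes", "y"):
        return True
    if lowered in ("0", "false", "f", "no", "n"):
        return False
    raise ValueError(f"cannot parse detected flag {text!r}")


def write_monitoring_csv(records: Iterable[MonitoringRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["station", "date", "parameter", "value", "detected", "detection_limit"]
        )
        for r in records:
            writer.writerow(
                [
                    r.station,
                    r.date.isoformat(),
                    r.parameter,
                    "" if r.value is None else repr(r.value),
                    int(r.detected),
                    "" if r.detection_limit is None else repr(r.detection_limit),
                ]
            )


def _policy_value(record: MonitoringRecord, policy: CensoringPolicy) -> float | None:
    if record.detected:
        return record.value
    if policy is CensoringPolicy.DETECTED_ONLY:
        return None
    if policy is CensoringPolicy.SUBSTITUTE_ZERO:
        return 0.0
    if policy is CensoringPolicy.SUBSTITUTE_HALF_DL:
        return record.detection_limit / 2.0
    return record.detection_limit


def summarize(
    records: Sequence[MonitoringRecord],
    policy: CensoringPolicy | str = CensoringPolicy.DETECTED_ONLY,
) -> list[SummaryStats]:
    """Summary statistics per station x parameter under a censoring policy.

    Returns one :class:`SummaryStats` per (station, parameter) group, sorted
    by station then parameter. Groups whose policy-selected value set is
    empty (every sample censored under ``detected_only``) come back flagged
    ``no_data`` rather than raising.
    """
    policy = CensoringPolicy(policy)
    groups: dict[tuple[str, str], list[MonitoringRecord]] = {}
    for rec in records:
        groups.setdefault((rec.station, rec.parameter), []).append(rec)

    out: list[SummaryStats] = []
    for (station, parameter), group in sorted(groups.items()):
        values = [
            v for r in group if (v := _policy_value(r, policy)) is not None
        ]
        n_detected = sum(r.detected for r in group)
        if values:
            out.append(
                SummaryStats(
                    station=station,
                    parameter=parameter,
                    n=len(group),
                    n_detected=n_detected,
                    mean=math.fsum(values) / len(values),  # order-invariant
                    minimum=min(values),
                    maximum=max(values),
                    policy=policy,
                )
            )
        else:
            out.append(
                SummaryStats(
                    station=station,
                    parameter=parameter,
                    n=len(group),
                    n_detected=n_detected,
                    mean=None,
                    minimum=None,
                    maximum=None,
                    policy=policy,
                )
            )
    return out


def summaries_to_frame(summaries: Sequence[SummaryStats]) -> pd.DataFrame:
    """Tidy DataFrame view of summaries (one row per station x parameter)."""
    return pd.DataFrame(
        [
            {
                "station": s.station,
                "parameter": s.parameter,
                "n": s.n,
                "n_detected": s.n_detected,
                "mean": s.mean,
                "minimum": s.minimum,
                "maximum": s.maximum,
                "policy": s.policy.value,
            }
            for s in summaries
        ]
    )
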