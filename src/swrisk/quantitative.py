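"""Hazard-quotient screening of monitoring summaries against standards.

The hazard quotient (HQ) is the ratio of an expected exposure concentration
to the safe threshold for that parameter:

    HQ = exposure / threshold

HQ > 1 means the exposure exceeds the allowable limit. For a chronic screen
the station mean is the exposure (``hq_avg``); the station maximum gives the
acute, worst-sample screen (``hq_max``). Parameters whose standard is a
lower limit (dissolved oxygen) or a two-sided range (pH) have no meaningful
ratio against an upper bound; they are reported with absent HQs — rendered
"-" in tables — plus the fraction of samples inside the safe range.

Quotients are carried unrounded through the pipeline; the reporting layer
rounds half-up to two decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._util import round_half_up
from .monitoring import SummaryStats
from .standards import Standard, StandardKind, StandardRegistry

__all__ = [
    "HazardResult",
    "hazard_quotient",
    "range_compliance",
    "hq_table",
    "hazard_results_to_frame",
]


def hazard_quotient(exposure: float, threshold: float) -> float:
    """Exposure / threshold ratio; > 1 flags an exceedance.

    Parameters
    ----------
    exposure : measured or summarised concentration, >= 0.
    threshold : safe upper limit, > 0.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if exposure < 0:
        raise ValueError(f"exposure must be non-negative, got {exposure}")
    return exposure / threshold


def range_compliance(values: Sequence[float], standard: Standard) -> float | None:
    """Fraction of values inside the safe range of a range/lower-limit standard.

    Returns ``None`` (a no-data flag) for an empty value collection.
    """
    kind = standard.parameter.kind
    if kind is StandardKind.UPPER_LIMIT:
        raise ValueError("range_compliance applies to range/lower-limit standards")
    values = list(values)
    if not values:
        return None
    if kind is StandardKind.LOWER_LIMIT:
        ok = sum(v >= standard.lower for v in values)
    else:
        ok = sum(standard.lower <= v <= standard.upper for v in values)
    return ok / len(values)


@dataclass(frozen=True)
class HazardResult:
    """HQ pair (upper-limit parameters) or range compliance (pH, DO)."""

    station: str
    parameter: str
    kind: StandardKind
    threshold: float | None = None
    hq_avg: float | None = None
    hq_max: float | None = None
    range_compliant_fraction: float | None = None
    no_data: bool = False

    @property
    def exceeds_avg(self) -> bool:
        return self.hq_avg is not None and self.hq_avg > 1.0

    @property
    def exceeds_max(self) -> bool:
        return self.hq_max is not None and self.hq_max > 1.0


def hq_table(
    summaries: Sequence[SummaryStats],
    registry: StandardRegistry,
    standard_set: str = "class_a",
    values_by_group: dict[tuple[str, str], Sequence[float]] | None = None,
) -> list[HazardResult]:
    """Screen every summary against one standard set.

    Upper-limit parameters get ``hq_avg = mean/threshold`` and
    ``hq_max = max/threshold``. Range and lower-limit parameters get absent
    HQs plus ``range_compliant_fraction``: exact when raw sample values are
    supplied in ``values_by_group`` (keyed by (station, parameter)), else
    1.0 when the summary's [min, max] envelope lies inside the safe range
    and ``None`` (indeterminate from a summary alone) otherwise. Summaries
    whose parameter has no standard in the set are skipped with a warning.
    """
    results: list[HazardResult] = []
    for s in summaries:
        std = registry.get(s.parameter, standard_set)
        if std is None:
            warnings.warn(
                f"no {standard_set!r} standard for parameter {s.parameter!r}; "
                "skipped",
                stacklevel=2,
            )
            continue
        kind = std.parameter.kind
        if s.no_data:
            results.append(
                HazardResult(
                    station=s.station, parameter=s.parameter, kind=kind,
                    threshold=std.upper, no_data=True,
                )
            )
            continue
        if kind is StandardKind.UPPER_LIMIT:
            results.append(
                HazardResult(
                    station=s.station,
                    parameter=s.parameter,
                    kind=kind,
                    threshold=std.upper,
                    hq_avg=hazard_quotient(s.mean, std.upper),
                    hq_max=hazard_quotient(s.maximum, std.upper),
                )
            )
        else:
            raw = None
            if values_by_group is not None:
                raw = values_by_group.get((s.station, s.parameter))
            if raw is not None:
                fraction = range_compliance(raw, std)
            else:
                fraction = 1.0 if _envelope_compliant(s, std) else None
            results.append(
                HazardResult(
                    station=s.station,
                    parameter=s.parameter,
                    kind=kind,
                    threshold=None,
                    range_compliant_fraction=fraction,
                )
            )
    return results


def _envelope_compliant(s: SummaryStats, std: Standard) -> bool:
    if std.parameter.kind is StandardKind.LOWER_LIMIT:
        return s.minimum >= std.lower
    return s.minimum >= std.lower and s.maximum <= std.upper


def hazard_results_to_frame(results: Sequence[HazardResult]) -> pd.DataFrame:
    """Reporting view: HQs rounded half-up to 2 decimals, absent HQs as '-'."""
    rows = []
    for r in results:
        rows.append(
            {
                "station": r.station,
                "parameter": r.parameter,
                "threshold": r.threshold if r.threshold is not None else "-",
                "hq_avg": "-" if r.hq_avg is None else round_half_up(r.hq_avg, 2),
                "hq_max": "-" if r.hq_max is None else round_half_up(r.hq_max, 2),
                "range_compliant_fraction": (
                    "" if r.range_compliant_fraction is None
                    else r.range_compliant_fraction
                ),
                "exceeds_avg": r.exceeds_avg,
                "exceeds_max": r.exceeds_max,
                "no_data": r.no_data,
            }
        )
    return pd.DataFrame(rows)
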