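"""Qualitative S x P x E risk matrix with four-band classification.

Each potential pollution source in a sub-watershed is scored on three
factors, each on a 1–4 scale:

``S`` — source characteristics: pathogen sources outrank non-pathogenic
    ones, major sources outrank minor ones (pathogen+major = 4 down to
    non-pathogen+minor = 1);
``P`` — proximity to water: the riparian buffer zone the activity occupies
    (0–50 m = 4, 50–250 m = 3, 250–1,000 m = 2, >1,000 m = 1);
``E`` — spatial extent: the activity's area as a percent of its
    sub-watershed (>=1% = 4, 0.1–1% = 3, 0.01–0.1% = 2, <0.01% = 1).

The per-zone product R = S x P x E (range 1–64) is averaged over occupied
zones and the aggregate classified into four bands: low (<=6), medium
(<=9), high (<=16), very high (>16). The scale is comparative — it ranks
activities for further investigation; R = 64 does not mean four times the
risk of R = 16.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .spatial import Zone, ZoneExposure

__all__ = [
    "RiskBand",
    "SourceCharacterization",
    "ZoneAssessment",
    "QualitativeRisk",
    "source_level",
    "proximity_level",
    "extent_level",
    "zone_risk",
    "aggregate_risk",
    "risk_band",
    "assess",
    "rollup_sources",
]


class RiskBand(str, Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"
    VERY_HIGH = "very_high"


def source_level(pathogen_source: bool, major_source: bool) -> int:
    """S level from the two source attributes (pathogen/major -> 4 .. 1)."""
    return 1 + 2 * bool(pathogen_source) + 1 * bool(major_source)


def proximity_level(zone: Zone) -> int:
    """P level: innermost zone (0-50 m) scores 4, outermost (>1000 m) scores 1."""
    return 5 - zone.index


def extent_level(percent: float) -> int:
    """E level from percent of sub-watershed occupied.

    Bins are lower-inclusive: <0.01 -> 1; [0.01, 0.1) -> 2; [0.1, 1) -> 3;
    >= 1 -> 4 (extents above 10% clamp to 4).
    """
    if percent < 0:
        raise ValueError(f"percent must be non-negative, got {percent}")
    if percent < 0.01:
        return 1
    if percent < 0.1:
        return 2
    if percent < 1.0:
        return 3
    return 4


def zone_risk(s: int, p: int, e: int) -> int:
    """Per-zone product R = S x P x E."""
    for name, level in (("S", s), ("P", p), ("E", e)):
        if not (isinstance(level, int) and 1 <= level <= 4):
            raise ValueError(f"{name} level must be an integer in 1..4, got {level}")
    return s * p * e


def aggregate_risk(
    zone_risks: Sequence[float],
    zone_areas: Sequence[float],
    include_empty_zones: bool = False,
) -> float | None:
    """Unweighted mean of per-zone R over zones where the activity is present.

    Zones with zero activity area are excluded (their R is vacuous) unless
    ``include_empty_zones`` forces strict all-zone averaging. Returns
    ``None`` when no zone has any activity area — no exposure, no risk.
    """
    if len(zone_risks) != len(zone_areas):
        raise ValueError("zone_risks and zone_areas must have equal length")
    if include_empty_zones:
        included = list(zone_risks)
    else:
        included = [r for r, a in zip(zone_risks, zone_areas) if a > 0]
    if not included:
        return None
    return sum(included) / len(included)


def risk_band(r: float) -> RiskBand:
    """Band for an aggregate score: low <=6 < medium <=9 < high <=16 < very high."""
    if r < 0:
        raise ValueError(f"risk score must be non-negative, got {r}")
    if r <= 6:
        return RiskBand.LOW
    if r <= 9:
        return RiskBand.MEDIUM
    if r <= 16:
        return RiskBand.HIGH
    return RiskBand.VERY_HIGH


@dataclass(frozen=True)
class SourceCharacterization:
    """A potential pollution source and its S-level attributes.

    ``proximity_override`` / ``extent_override`` pin P or E to a declared
    level instead of computing them from geometry — used for point-like
    activities (e.g. recreation spots: small extent, E = 1, but always by
    the stream, P = 4) where areal percentages are not meaningful.
    """

    name: str
    pathogen_source: bool
    major_source: bool
    proximity_override: int | None = None
    extent_override: int | None = None

    @property
    def s_level(self) -> int:
        return source_level(self.pathogen_source, self.major_source)


@dataclass(frozen=True)
class ZoneAssessment:
    zone: Zone
    activity_area_m2: float
    percent: float
    p_level: int
    e_level: int
    r: int


@dataclass(frozen=True)
class QualitativeRisk:
    """Full per-source qualitative assessment of one sub-watershed."""

    subwatershed: str
    source: SourceCharacterization
    zones: tuple[ZoneAssessment, ...]
    aggregate_r: float | None
    band: RiskBand
    no_exposure: bool = False


def assess(
    exposures: Sequence[ZoneExposure],
    source: SourceCharacterization,
    include_empty_zones: bool = False,
) -> QualitativeRisk:
    """Score one source in one sub-watershed from its zone exposures.

    ``exposures`` must all belong to one sub-watershed and one activity
    class (typically the four rows a zone tabulation yields). Per zone the
    percent of sub-watershed area gives E, the zone itself gives P, and
    R = S x P x E; the aggregate is the unweighted mean over occupied zones
    and sets the band. An all-zero exposure comes back flagged
    ``no_exposure`` with band low.
    """
    if not exposures:
        raise ValueError("no exposures given")
    subs = {e.subwatershed for e in exposures}
    classes = {e.activity_class for e in exposures}
    if len(subs) != 1 or len(classes) != 1:
        raise ValueError(
            f"exposures must share one sub-watershed and class, got {subs}, {classes}"
        )
    zones_seen = [e.zone for e in exposures]
    if len(set(zones_seen)) != len(zones_seen):
        raise ValueError("duplicate zone in exposures")

    s = source.s_level
    assessments = []
    for exp in sorted(exposures, key=lambda e: e.zone.index):
        p = (
            source.proximity_override
            if source.proximity_override is not None
            else proximity_level(exp.zone)
        )
        e_lvl = (
            source.extent_override
            if source.extent_override is not None
            else extent_level(exp.percent)
        )
        assessments.append(
            ZoneAssessment(
                zone=exp.zone,
                activity_area_m2=exp.activity_area_m2,
                percent=exp.percent,
                p_level=p,
                e_level=e_lvl,
                r=zone_risk(s, p, e_lvl),
            )
        )

    agg = aggregate_risk(
        [a.r for a in assessments],
        [a.activity_area_m2 for a in assessments],
        include_empty_zones=include_empty_zones,
    )
    if agg is None:
        band, no_exposure = RiskBand.LOW, True
    else:
        band, no_exposure = risk_band(agg), False
    return QualitativeRisk(
        subwatershed=next(iter(subs)),
        source=source,
        zones=tuple(assessments),
        aggregate_r=agg,
        band=band,
        no_exposure=no_exposure,
    )


def rollup_sources(risks: Sequence[QualitativeRisk]) -> tuple[float | None, RiskBand]:
    """Combine several sources of one sub-watershed into one score.

    Interpretive convenience: the unweighted mean of the sources' aggregate
    scores (no-exposure sources excluded), banded like a single source.
    """
    scores = [r.aggregate_r for r in risks if r.aggregate_r is not None]
    if not scores:
        return None, RiskBand.LOW
    mean = sum(scores) / len(scores)
    return mean, risk_band(mean)
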