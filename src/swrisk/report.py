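"""Integrated reporting: pollutant ranking, sub-watershed ranking, land use.

Joins the quantitative screen and qualitative matrix into the tables a
watershed manager acts on: which parameters exceed their thresholds most
(chronic screen, ranked by the worst station's average HQ), which
sub-watershed/source combinations carry the highest qualitative band, and
how land use is distributed per basin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._util import round_half_up
from .qualitative import QualitativeRisk
from .quantitative import HazardResult, hazard_results_to_frame

__all__ = [
    "IntegratedReport",
    "rank_pollutants",
    "rank_subwatersheds",
    "landuse_percentages",
    "render_reports",
]


def rank_pollutants(results: Sequence[HazardResult]) -> pd.DataFrame:
    """Rank upper-limit parameters by descending max-over-stations hq_avg.

    Ties break on hq_max, then parameter name. Range/lower-limit parameters
    (no HQ) are returned separately in a trailing block with null HQs so
    nothing silently drops out of the report.
    """
    with_hq = [r for r in results if r.hq_avg is not None]
    without_hq = [r for r in results if r.hq_avg is None]

    rows = []
    by_param: dict[str, list[HazardResult]] = {}
    for r in with_hq:
        by_param.setdefault(r.parameter, []).append(r)
    for param, group in by_param.items():
        best = max(group, key=lambda r: (r.hq_avg, r.hq_max))
        rows.append(
            {
                "parameter": param,
                "hq_avg": best.hq_avg,
                "hq_max": best.hq_max,
                "station": best.station,
            }
        )
    rows.sort(key=lambda row: (-row["hq_avg"], -row["hq_max"], row["parameter"]))

    seen = set()
    for r in without_hq:
        if r.parameter in seen:
            continue
        seen.add(r.parameter)
        rows.append(
            {"parameter": r.parameter, "hq_avg": None, "hq_max": None, "station": ""}
        )
    df = pd.DataFrame(rows, columns=["parameter", "hq_avg", "hq_max", "station"])
    df.insert(0, "rank", range(1, len(df) + 1))
    return df


def rank_subwatersheds(risks: Sequence[QualitativeRisk]) -> pd.DataFrame:
    """Order (sub-watershed, source) assessments by descending aggregate score."""
    rows = [
        {
            "subwatershed": r.subwatershed,
            "source": r.source.name,
            "aggregate_r": r.aggregate_r,
            "band": r.band.value,
            "no_exposure": r.no_exposure,
        }
        for r in risks
    ]
    rows.sort(
        key=lambda row: (
            -(row["aggregate_r"] if row["aggregate_r"] is not None else -1.0),
            row["subwatershed"],
            row["source"],
        )
    )
    return pd.DataFrame(
        rows, columns=["subwatershed", "source", "aggregate_r", "band", "no_exposure"]
    )


def landuse_percentages(
    areas: pd.DataFrame, totals: pd.Series | None = None
) -> pd.DataFrame:
    """Percent of each basin occupied by each land-use class.

    ``areas`` is class x basin in km² (a ``Total`` row, if present, is used
    as the denominator and retained). ``totals`` overrides the denominators.
    Percentages are rounded half-up to 1 decimal, matching survey tables.
    """
    areas = areas.copy()
    if totals is None:
        if "Total" in areas.index:
            totals = areas.loc["Total"]
        else:
            totals = areas.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("basin totals must be positive")
    classes = areas.drop(index="Total", errors="ignore")
    percent = classes.divide(totals, axis=1) * 100.0
    percent = percent.map(lambda x: round_half_up(x, 1))
    out = pd.concat(
        {"area_km2": classes, "percent": percent}, axis=1
    ).swaplevel(axis=1).sort_index(axis=1, level=0)
    out = out.reindex(
        columns=pd.MultiIndex.from_product(
            [classes.columns, ["area_km2", "percent"]]
        )
    )
    return out


@dataclass
class IntegratedReport:
    """The assembled report tables (see the renderers for file layouts)."""

    hazard_results: Sequence[HazardResult]
    qualitative_risks: Sequence[QualitativeRisk]
    landuse_areas: pd.DataFrame | None = None

    @property
    def pollutant_ranking(self) -> pd.DataFrame:
        return rank_pollutants(self.hazard_results)

    @property
    def subwatershed_ranking(self) -> pd.DataFrame:
        return rank_subwatersheds(self.qualitative_risks)

    @property
    def landuse_table(self) -> pd.DataFrame | None:
        if self.landuse_areas is None:
            return None
        return landuse_percentages(self.landuse_areas)


def _qualitative_frame(risks: Sequence[QualitativeRisk]) -> pd.DataFrame:
    rows = []
    for r in risks:
        for za in r.zones:
            rows.append(
                {
                    "subwatershed": r.subwatershed,
                    "source": r.source.name,
                    "s_level": r.source.s_level,
                    "zone": za.zone.label,
                    "activity_area_m2": za.activity_area_m2,
                    "percent": round_half_up(za.percent, 1),
                    "p_level": za.p_level,
                    "e_level": za.e_level,
                    "r": za.r,
                    "aggregate_r": r.aggregate_r,
                    "band": r.band.value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subwatershed", "source", "s_level", "zone", "activity_area_m2",
            "percent", "p_level", "e_level", "r", "aggregate_r", "band",
        ],
    )


def render_reports(report: IntegratedReport, out_dir: str | Path) -> list[Path]:
    """Write the report CSVs; byte-identical output for identical inputs.

    Emits ``hq_table.csv`` (screening layout: one row per station x
    parameter with rounded HQ columns), ``qualitative.csv`` (one row per
    zone per source with S/P/E/R and the aggregate), ``ranking.csv``
    (pollutant ranking) and, when land-use areas were supplied,
    ``landuse.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    hq_path = out_dir / "hq_table.csv"
    hazard_results_to_frame(list(report.hazard_results)).to_csv(
        hq_path, index=False, lineterminator="\n"
    )
    written.append(hq_path)

    qual_path = out_dir / "qualitative.csv"
    _qualitative_frame(list(report.qualitative_risks)).to_csv(
        qual_path, index=False, lineterminator="\n"
    )
    written.append(qual_path)

    rank_path = out_dir / "ranking.csv"
    ranking = report.pollutant_ranking.copy()
    for col in ("hq_avg", "hq_max"):
        ranking[col] = ranking[col].map(
            lambda x: "" if pd.isna(x) else round_half_up(x, 2)
        )
    ranking.to_csv(rank_path, index=False, lineterminator="\n")
    written.append(rank_path)

    if report.landuse_areas is not None:
        lu_path = out_dir / "landuse.csv"
        report.landuse_table.to_csv(lu_path, lineterminator="\n")
        written.append(lu_path)
    return written
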