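"""Synthetic inputs and the TSWA case-study fixtures.

Two generators produce inputs with the structure the pipeline assumes:

* :func:`gen_monitoring` — monthly grab samples per station and parameter.
  Concentrations are lognormal (strictly positive and right-skewed, the
  pattern of real water-quality data where the mean sits far below the
  maximum) with an optional multiplicative sinusoidal seasonal cycle
  (emulating summer peaks in suspended solids driven by rainfall). Draws
  below the detection limit become non-detects.
* :func:`gen_watershed` — a raster watershed: a rasterized stream polyline,
  a background land-use class with rectangular activity patches, and an
  axis-aligned partition into sub-watersheds.

Both are deterministic under a fixed seed.

The ``tswa_*`` functions ship the printed summary tables of the Taipei
Source Water Area case study (station screening summaries, the A002
tea-growing zone areas, basin land-use areas, sub-watershed attributes)
verbatim as ready-made pipeline inputs; nothing in them is simulated or
interpolated.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .monitoring import CensoringPolicy, MonitoringRecord, SummaryStats
from .spatial import Zone, ZoneExposure, WatershedGrid

__all__ = [
    "ParameterModel",
    "MonitoringGeneratorSpec",
    "StreamPolyline",
    "Patch",
    "WatershedGeneratorSpec",
    "gen_monitoring",
    "gen_watershed",
    "tswa_summaries",
    "tswa_printed_hq",
    "tswa_zone_areas",
    "tswa_landuse",
    "tswa_attributes",
    "tswa_fixtures",
]


# ---------------------------------------------------------------------------
# Monitoring generator

@dataclass(frozen=True)
class ParameterModel:
    """Lognormal concentration model for one parameter.

    ``mu``/``sigma`` are on the natural-log scale; ``detection_limit`` in
    parameter units (0 = everything detected); ``seasonal_amplitude`` is the
    fractional peak-to-mean modulation and ``phase_month`` the calendar
    month (1-12) of the seasonal peak.
    """

    mu: float
    sigma: float
    units: str = "mg/L"
    detection_limit: float = 0.0
    seasonal_amplitude: float = 0.0
    phase_month: int = 7

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.detection_limit < 0:
            raise ValueError("detection limit must be non-negative")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal amplitude must be non-negative")


#: Default parameter models, chosen so generated summaries have the order of
#: magnitude of raw-water monitoring in a forested source-water area
#: (coliforms in the thousands of CFU/100 mL with occasional spikes, TP tens
#: of ug/L hovering near its detection limit, SS peaking in summer).
DEFAULT_PARAMETERS: dict[str, ParameterModel] = {
    "Total coliforms": ParameterModel(
        mu=math.log(800.0), sigma=1.5, units="CFU/100 mL", detection_limit=10.0
    ),
    "Total phosphorus": ParameterModel(
        mu=math.log(0.03), sigma=0.8, detection_limit=0.013
    ),
    "Ammonia nitrogen": ParameterModel(
        mu=math.log(0.04), sigma=0.9, detection_limit=0.01
    ),
    "Suspended solids": ParameterModel(
        mu=math.log(8.0), sigma=1.0, detection_limit=0.5,
        seasonal_amplitude=0.6, phase_month=7,
    ),
    "Biochemical oxygen demand": ParameterModel(
        mu=math.log(1.0), sigma=0.5, detection_limit=0.3
    ),
}


@dataclass(frozen=True)
class MonitoringGeneratorSpec:
    """Monthly monitoring campaign: which stations, which parameters, how long."""

    stations: tuple[str, ...] = ("A008", "B006", "C003")
    parameters: dict[str, ParameterModel] = field(
        default_factory=lambda: dict(DEFAULT_PARAMETERS)
    )
    n_months: int = 36
    start: _dt.date = _dt.date(2008, 1, 15)
    seed: int = 0


def _month_sequence(start: _dt.date, n_months: int) -> list[_dt.date]:
    out = []
    year, month = start.year, start.month
    for _ in range(n_months):
        day = min(start.day, calendar.monthrange(year, month)[1])
        out.append(_dt.date(year, month, day))
        month += 1
        if month > 12:
            month, year = 1, year + 1
    return out


def gen_monitoring(spec: MonitoringGeneratorSpec) -> list[MonitoringRecord]:
    """Draw a monthly monitoring record set; same seed, same records.

    Each record's concentration is
    ``exp(N(mu, sigma)) * (1 + A * sin(2*pi*(month - phase)/12))``; draws
    below the detection limit are emitted as non-detects carrying the limit.
    """
    rng = np.random.default_rng(spec.seed)
    dates = _month_sequence(spec.start, spec.n_months)
    records: list[MonitoringRecord] = []
    for station in spec.stations:
        for pname, model in spec.parameters.items():
            draws = rng.lognormal(model.mu, model.sigma, size=len(dates))
            for date, draw in zip(dates, draws):
                season = 1.0 + model.seasonal_amplitude * math.sin(
                    2.0 * math.pi * (date.month - model.phase_month) / 12.0
                )
                value = draw * max(season, 0.0)
                if value < model.detection_limit:
                    records.append(
                        MonitoringRecord(
                            station=station, date=date, parameter=pname,
                            value=None, detected=False,
                            detection_limit=model.detection_limit,
                        )
                    )
                else:
                    records.append(
                        MonitoringRecord(
                            station=station, date=date, parameter=pname,
                            value=float(value), detected=True,
                            detection_limit=model.detection_limit or None,
                        )
                    )
    return records


# ---------------------------------------------------------------------------
# Watershed generator

@dataclass(frozen=True)
class StreamPolyline:
    """Stream course as metre-coordinate vertices on the grid."""

    vertices: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class Patch:
    """Axis-aligned activity rectangle in metre coordinates (x0,y0)-(x1,y1)."""

    activity_class: int
    x0: float
    y0: float
    x1: float
    y1: float


@dataclass(frozen=True)
class WatershedGeneratorSpec:
    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 10.0
    stream: StreamPolyline = StreamPolyline(((500.0, 0.0), (500.0, 1000.0)))
    patches: tuple[Patch, ...] = ()
    background_class: int = 1
    split_x: tuple[float, ...] = ()  # vertical sub-watershed split lines, metres
    split_y: tuple[float, ...] = ()
    seed: int = 0


def gen_watershed(spec: WatershedGeneratorSpec) -> WatershedGrid:
    """Rasterize the spec into aligned land-use / stream / sub-watershed layers.

    Cell (row 0, col 0) is the north-west corner; the cell at row i, col j
    has its center at x = (j + 0.5) * cell_size,
    y = (n_rows - i - 0.5) * cell_size. Later patches overwrite earlier
    ones. Patches must lie within the grid bounds.
    """
    width = spec.n_cols * spec.cell_size
    height = spec.n_rows * spec.cell_size

    landuse = np.full((spec.n_rows, spec.n_cols), spec.background_class, dtype=int)
    for patch in spec.patches:
        if not (0 <= patch.x0 < patch.x1 <= width and 0 <= patch.y0 < patch.y1 <= height):
            raise ValueError(f"patch {patch} out of grid bounds {width}x{height}")
        c0 = int(np.ceil(patch.x0 / spec.cell_size - 0.5))
        c1 = int(np.floor(patch.x1 / spec.cell_size - 0.5))
        r1 = spec.n_rows - 1 - int(np.ceil(patch.y0 / spec.cell_size - 0.5))
        r0 = spec.n_rows - 1 - int(np.floor(patch.y1 / spec.cell_size - 0.5))
        landuse[r0 : r1 + 1, c0 : c1 + 1] = patch.activity_class

    stream_mask = np.zeros((spec.n_rows, spec.n_cols), dtype=bool)
    verts = spec.stream.vertices
    for (xa, ya), (xb, yb) in zip(verts[:-1], verts[1:]):
        seg_len = math.hypot(xb - xa, yb - ya)
        n_steps = max(int(seg_len / (spec.cell_size / 2.0)), 1)
        for t in np.linspace(0.0, 1.0, n_steps + 1):
            x = xa + t * (xb - xa)
            y = ya + t * (yb - ya)
            col = min(max(int(x / spec.cell_size), 0), spec.n_cols - 1)
            row = min(max(spec.n_rows - 1 - int(y / spec.cell_size), 0), spec.n_rows - 1)
            stream_mask[row, col] = True

    # sub-watershed label = 1 + block index in the (split_x x split_y) partition
    cols = np.arange(spec.n_cols) + 0.5
    rows = np.arange(spec.n_rows) + 0.5
    x_centers = cols * spec.cell_size
    y_centers = (spec.n_rows - rows) * spec.cell_size
    x_block = np.searchsorted(np.asarray(spec.split_x), x_centers)
    y_block = np.searchsorted(np.asarray(spec.split_y), y_centers)
    n_x = len(spec.split_x) + 1
    sub = 1 + y_block[:, None] * n_x + x_block[None, :]

    return WatershedGrid(
        landuse=landuse,
        stream_mask=stream_mask,
        subwatershed_id=sub,
        cell_size=spec.cell_size,
    )


# ---------------------------------------------------------------------------
# TSWA case-study fixtures (printed values, embedded verbatim)

# station, parameter, n, n_detected, mean, min, max, printed HQ avg, printed HQ max
_TSWA_SCREEN_TABLE: tuple = (
    ("A008", "Total coliforms", 32, 29, 2741.0, 30.0, 58000.0, 54.82, 1160.00),
    ("A008", "Total phosphorus", 32, 21, 0.028, 0.013, 0.093, 1.42, 4.65),
    ("A008", "Ammonia nitrogen", 32, 20, 0.048, 0.01, 0.2, 0.48, 2.00),
    ("A008", "Suspended solids", 32, 29, 5.45, 1.3, 36.1, 0.22, 1.44),
    ("A008", "Biochemical oxygen demand", 32, 32, 1.06, 0.3, 3.8, 1.06, 3.80),
    ("A008", "Dissolved oxygen", 32, 32, 7.49, 6.5, 8.8, None, None),
    ("A008", "pH", 32, 32, 7.51, 6.7, 8.5, None, None),
    ("B006", "Total coliforms", 32, 32, 3048.0, 95.0, 37000.0, 60.96, 740.00),
    ("B006", "Total phosphorus", 32, 29, 0.049, 0.015, 0.287, 2.45, 14.35),
    ("B006", "Ammonia nitrogen", 32, 22, 0.035, 0.01, 0.17, 0.35, 1.70),
    ("B006", "Suspended solids", 32, 29, 30.02, 1.1, 345.0, 1.20, 13.80),
    ("B006", "Biochemical oxygen demand", 32, 32, 0.94, 0.4, 3.3, 0.94, 3.30),
    ("B006", "Dissolved oxygen", 32, 32, 7.78, 6.6, 8.6, None, None),
    ("B006", "pH", 32, 32, 8.11, 7.0, 9.0, None, None),
    ("C003", "Total coliforms", 36, 36, 1111.1, 25.0, 7500.0, 22.22, 150.00),
    ("C003", "Total phosphorus", 35, 29, 0.093, 0.015, 0.58, 4.65, 29.00),
    ("C003", "Ammonia nitrogen", 36, 26, 0.135, 0.01, 1.7, 1.35, 17.00),
    ("C003", "Suspended solids", 36, 35, 15.66, 0.6, 126.0, 0.63, 5.04),
    ("C003", "Biochemical oxygen demand", 36, 36, 1.04, 0.3, 6.9, 1.04, 6.90),
    ("C003", "Dissolved oxygen", 36, 36, 7.85, 6.3, 10.2, None, None),
    ("C003", "pH", 36, 36, 7.54, 6.5, 8.7, None, None),
)


def tswa_summaries() -> list[SummaryStats]:
    """Screening summaries for the three treatment-plant intake stations."""
    return [
        SummaryStats(
            station=st, parameter=par, n=n, n_detected=nd,
            mean=mean, minimum=mn, maximum=mx,
            policy=CensoringPolicy.DETECTED_ONLY,
        )
        for st, par, n, nd, mean, mn, mx, _, _ in _TSWA_SCREEN_TABLE
    ]


def tswa_printed_hq() -> dict[tuple[str, str], tuple[float | None, float | None]]:
    """The published HQ columns, keyed by (station, parameter).

    Note: the A008 total-phosphorus average quotient (1.42) traces to the
    unrounded station mean (~0.0284); the tabulated mean is printed to
    three decimals as 0.028, which yields 1.40.
    """
    return {
        (st, par): (hq_a, hq_m)
        for st, par, *_rest, hq_a, hq_m in _TSWA_SCREEN_TABLE
    }


_TSWA_A002_ZONE_AREAS = {
    Zone.ZONE_0_50: 71_267.0,
    Zone.ZONE_50_250: 374_034.0,
    Zone.ZONE_250_1000: 810_881.0,
    Zone.ZONE_BEYOND_1000: 450_905.0,
}
_TSWA_A002_TOTAL_AREA = 12_012_334.0


def tswa_zone_areas() -> list[ZoneExposure]:
    """Tea-growing areas per buffer zone in sub-watershed A002 (m^2)."""
    return [
        ZoneExposure(
            subwatershed="A002",
            activity_class="tea",
            zone=zone,
            activity_area_m2=area,
            subwatershed_area_m2=_TSWA_A002_TOTAL_AREA,
        )
        for zone, area in _TSWA_A002_ZONE_AREAS.items()
    ]


def tswa_landuse() -> pd.DataFrame:
    """Land-use areas (km^2) per basin, with the published basin totals.

    Index: land-use class; columns: the three creek basins plus ``Total``.
    The ``Total`` row carries the published basin totals (which reflect the
    survey's own rounding, e.g. Bei-Shih classes sum to 316.99 vs a printed
    total of 316.9).
    """
    data = {
        "Bei-Shih": [4.38, 277.14, 18.84, 4.24, 12.39, 316.9],
        "Nan-Shih": [1.75, 328.65, 1.44, 1.02, 2.58, 335.44],
        "Sin-Dian": [4.13, 33.66, 5.77, 0.12, 1.46, 45.14],
        "Total": [10.26, 639.45, 26.05, 5.38, 16.43, 697.57],
    }
    index = [
        "Built-up area",
        "Forest",
        "Farmland",
        "Non-irrigated farmland without vegetative cover",
        "Water area",
        "Total",
    ]
    return pd.DataFrame(data, index=pd.Index(index, name="landuse"))


_TSWA_ATTRIBUTES = (
    # basin, sub-watershed, slope deg, total km2, tea km2, tea %, built km2, built %, people/km2
    ("Bei-Shih", "A001", 21.66, 42.89, 0.789, 1.84, 0.53, 1.24, 19),
    ("Bei-Shih", "A002", 22.41, 12.01, 1.707, 14.21, 0.64, 5.33, 123),
    ("Bei-Shih", "A003", 25.45, 36.87, 0.109, 0.30, 0.2, 0.54, 8),
    ("Bei-Shih", "A004", 25.85, 43.21, 1.407, 3.26, 0.43, 1.00, 43),
    ("Bei-Shih", "A005", 23.31, 1.13, 0.145, 12.82, 0.03, 2.65, 301),
    ("Bei-Shih", "A006", 23.58, 24.96, 1.518, 6.08, 0.24, 0.96, 33),
    ("Bei-Shih", "A007", 25.32, 2.15, 0.162, 7.55, 0.06, 2.79, 34),
    ("Bei-Shih", "A008", 26.71, 1.02, 0.010, 1.01, 0.0, 0.00, 11),
    ("Bei-Shih", "A009", 15.46, 11.97, 0.170, 1.42, 0.08, 0.67, 13),
    ("Bei-Shih", "A010", 23.34, 21.12, 0.064, 0.30, 0.04, 0.19, 12),
    ("Bei-Shih", "A011", 25.35, 26.37, 2.573, 9.76, 0.6, 2.28, 41),
    ("Bei-Shih", "A012", 21.99, 3.04, 0.238, 7.83, 0.14, 4.61, 25),
    ("Nan-Shih", "B001", 30.13, 163.99, 0.014, 0.01, 0.23, 0.14, 3),
    ("Nan-Shih", "B002", 30.22, 66.36, 0.184, 0.28, 0.92, 1.39, 31),
    ("Nan-Shih", "B003", 28.62, 83.78, 0.005, 0.01, 0.19, 0.23, 14),
    ("Nan-Shih", "B004", 24.65, 0.42, 0.001, 0.29, 0.03, 7.14, 117),
    ("Nan-Shih", "B005", 26.56, 2.69, 0.010, 0.38, 0.08, 2.97, 99),
    ("Nan-Shih", "B006", 28.13, 18.21, 0.115, 0.63, 0.3, 1.65, 110),
    ("Sin-Dian", "C001", 26.14, 19.66, 0.174, 0.89, 0.27, 1.37, 59),
    ("Sin-Dian", "C002", 24.26, 90.27, 1.621, 1.80, 1.39, 1.54, 55),
    ("Sin-Dian", "C003", 22.06, 13.68, 0.411, 3.00, 2.44, 17.84, 249),
    ("Sin-Dian", "C004", 19.72, 11.81, 0.830, 7.03, 1.42, 12.02, 618),
)


def tswa_attributes() -> pd.DataFrame:
    """Sub-watershed attribute table (slope, areas, tea/built shares, density)."""
    return pd.DataFrame(
        _TSWA_ATTRIBUTES,
        columns=[
            "basin", "subwatershed", "slope_deg", "total_area_km2",
            "tea_area_km2", "tea_percent", "built_area_km2", "built_percent",
            "population_density",
        ],
    )


def tswa_fixtures() -> dict:
    """All case-study fixtures in one mapping (plus the default standards)."""
    from .standards import default_registry

    return {
        "standards": default_registry(),
        "summaries": tswa_summaries(),
        "printed_hq": tswa_printed_hq(),
        "zone_areas": tswa_zone_areas(),
        "landuse": tswa_landuse(),
        "attributes": tswa_attributes(),
    }
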