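"""Raster buffer-zone engine: distance to stream, zone binning, area tabulation.

The qualitative risk model scores an activity partly by where it sits
relative to the stream network. This module turns a land-use raster plus a
stream mask into those inputs: a per-cell Euclidean distance-to-stream
surface, a binning of distances into the four riparian buffer zones
(0–50 m, 50–250 m, 250–1,000 m, >1,000 m), and a tabulation of activity
area per zone per sub-watershed.

Distances are between cell centers (not flow-path distances). Zone bins are
closed on their upper edge: a cell exactly 50 m from the stream belongs to
the 0–50 m zone. Rasters travel as ESRI ASCII grids; NODATA cells are
excluded from all area tabulations. Areas are carried in m².
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Zone",
    "ZONE_UPPER_EDGES_M",
    "WatershedGrid",
    "ZoneExposure",
    "AsciiGrid",
    "GeometryError",
    "zone_of",
    "distance_to_stream",
    "zone_layer",
    "tabulate_zone_areas",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_zone_areas_csv",
    "write_zone_areas_csv",
]


class GeometryError(ValueError):
    """Raster layers disagree on grid geometry."""


class Zone(Enum):
    """Riparian buffer zones, ordered outward from the stream."""

    ZONE_0_50 = (1, "0-50 m", 0.0, 50.0)
    ZONE_50_250 = (2, "50-250 m", 50.0, 250.0)
    ZONE_250_1000 = (3, "250-1000 m", 250.0, 1000.0)
    ZONE_BEYOND_1000 = (4, ">1000 m", 1000.0, float("inf"))

    def __init__(self, index: int, label: str, inner: float, outer: float):
        self.index = index
        self.label = label
        self.inner_m = inner
        self.outer_m = outer

    @classmethod
    def from_label(cls, label: str) -> "Zone":
        for z in cls:
            if z.label == label:
                return z
        raise ValueError(f"unknown zone label {label!r}")


#: Upper edges of the inner three zones, metres (closed on the upper edge).
ZONE_UPPER_EDGES_M = (50.0, 250.0, 1000.0)


def zone_of(distance_m: float) -> Zone:
    """Buffer zone containing a distance-to-stream value.

    Bins are upper-inclusive: [0, 50], (50, 250], (250, 1000], (1000, inf).
    """
    if distance_m < 0:
        raise ValueError(f"distance must be non-negative, got {distance_m}")
    for zone in Zone:
        if distance_m <= zone.outer_m:
            return zone
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass
class WatershedGrid:
    """Aligned raster layers describing one watershed.

    All layers share shape; ``cell_size`` is the square cell edge in metres.
    ``landuse`` holds integer activity-class codes (0 = none),
    ``subwatershed_id`` integer labels (0 = outside any sub-watershed), and
    ``valid`` marks cells that carry data (NODATA cells are False and drop
    out of every tabulation).
    """

    landuse: np.ndarray
    stream_mask: np.ndarray
    subwatershed_id: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.landuse = np.asarray(self.landuse, dtype=int)
        self.stream_mask = np.asarray(self.stream_mask, dtype=bool)
        self.subwatershed_id = np.asarray(self.subwatershed_id, dtype=int)
        shapes = {self.landuse.shape, self.stream_mask.shape, self.subwatershed_id.shape}
        if self.valid is None:
            self.valid = np.ones(self.landuse.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        shapes.add(self.valid.shape)
        if len(shapes) != 1:
            raise GeometryError(f"layer shapes differ: {sorted(shapes)}")
        if self.cell_size <= 0:
            raise GeometryError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def n_rows(self) -> int:
        return self.landuse.shape[0]

    @property
    def n_cols(self) -> int:
        return self.landuse.shape[1]


def distance_to_stream(grid: WatershedGrid) -> np.ndarray:
    """Per-cell Euclidean distance (m) from each cell center to the nearest
    stream-cell center. Stream cells get 0.
    """
    if not grid.stream_mask.any():
        raise ValueError("grid has no stream cells; distance undefined")
    # EDT measures distance to the nearest zero of its input.
    return ndimage.distance_transform_edt(
        ~grid.stream_mask, sampling=grid.cell_size
    )


def zone_layer(grid: WatershedGrid, distances: np.ndarray | None = None) -> np.ndarray:
    """Integer zone index (1..4) per cell, using the upper-inclusive bins."""
    if distances is None:
        distances = distance_to_stream(grid)
    # side='left' makes each bin's upper edge inclusive
    return 1 + np.searchsorted(ZONE_UPPER_EDGES_M, distances, side="left")


@dataclass(frozen=True)
class ZoneExposure:
    """Activity area within one buffer zone of one sub-watershed."""

    subwatershed: str
    activity_class: int | str
    zone: Zone
    activity_area_m2: float
    subwatershed_area_m2: float

    def __post_init__(self) -> None:
        if self.activity_area_m2 < 0:
            raise ValueError("activity area must be non-negative")
        if self.subwatershed_area_m2 <= 0:
            raise ValueError("sub-watershed area must be positive")
        if self.activity_area_m2 > self.subwatershed_area_m2 * (1 + 1e-9):
            raise ValueError("activity area exceeds sub-watershed area")

    @property
    def percent(self) -> float:
        return 100.0 * self.activity_area_m2 / self.subwatershed_area_m2


def tabulate_zone_areas(
    grid: WatershedGrid,
    activity_class: int,
    distances: np.ndarray | None = None,
) -> list[ZoneExposure]:
    """Tabulate one activity class's area per buffer zone per sub-watershed.

    Every sub-watershed present in the grid yields four :class:`ZoneExposure`
    rows (one per zone), zero-area where the class is absent. Cell areas are
    exact integer multiples of ``cell_size²``, so the four zone areas of a
    sub-watershed sum exactly to the class's total area there.
    """
    zones = zone_layer(grid, distances)
    cell_area = grid.cell_size ** 2
    out: list[ZoneExposure] = []
    ids = np.unique(grid.subwatershed_id[grid.valid])
    for sid in ids[ids > 0]:
        in_sub = (grid.subwatershed_id == sid) & grid.valid
        sub_area = int(in_sub.sum()) * cell_area
        is_class = in_sub & (grid.landuse == activity_class)
        for zone in Zone:
            n_cells = int((is_class & (zones == zone.index)).sum())
            out.append(
                ZoneExposure(
                    subwatershed=str(sid),
                    activity_class=activity_class,
                    zone=zone,
                    activity_area_m2=n_cells * cell_area,
                    subwatershed_area_m2=sub_area,
                )
            )
    return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

@dataclass
class AsciiGrid:
    """One raster layer with ESRI ASCII grid header geometry."""

    data: np.ndarray
    cell_size: float
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999

    @property
    def valid(self) -> np.ndarray:
        return self.data != self.nodata


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path) -> AsciiGrid:
    """Read an ESRI ASCII grid (.asc). Integer layers round-trip losslessly."""
    header: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            m = re.match(r"\s*([A-Za-z_]+)\s+(\S+)", line)
            if m and m.group(1).lower() in _HEADER_KEYS + ("nodata_value",):
                header[m.group(1).lower()] = float(m.group(2))
            else:
                fh.seek(pos)
                break
        missing = [k for k in _HEADER_KEYS if k not in header]
        if missing:
            raise GeometryError(f"ASCII grid header missing {missing}")
        data = np.loadtxt(fh, ndmin=2)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise GeometryError(
            f"data shape {data.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    if np.all(data == np.round(data)):
        data = data.astype(int)
    return AsciiGrid(
        data=data,
        cell_size=header["cellsize"],
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        nodata=header.get("nodata_value", -9999),
    )


def write_ascii_grid(layer: AsciiGrid, path: str | Path) -> None:
    data = np.asarray(layer.data)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {data.shape[1]}\n")
        fh.write(f"nrows {data.shape[0]}\n")
        fh.write(f"xllcorner {layer.xllcorner:g}\n")
        fh.write(f"yllcorner {layer.yllcorner:g}\n")
        fh.write(f"cellsize {layer.cell_size:g}\n")
        fh.write(f"NODATA_value {layer.nodata:g}\n")
        fmt = "%d" if np.issubdtype(data.dtype, np.integer) else "%.10g"
        np.savetxt(fh, data, fmt=fmt)


def assemble_grid(
    landuse: AsciiGrid,
    stream: AsciiGrid,
    subwatershed: AsciiGrid | None = None,
) -> WatershedGrid:
    """Validate shared geometry and build a :class:`WatershedGrid`."""
    layers = [landuse, stream] + ([subwatershed] if subwatershed is not None else [])
    geoms = {
        (l.data.shape, l.cell_size, l.xllcorner, l.yllcorner) for l in layers
    }
    if len(geoms) != 1:
        raise GeometryError(f"layer geometries differ: {sorted(map(str, geoms))}")
    valid = landuse.valid & stream.valid
    sub = (
        subwatershed.data if subwatershed is not None
        else np.ones(landuse.data.shape, dtype=int)
    )
    lu = np.where(valid, landuse.data, 0)
    return WatershedGrid(
        landuse=lu,
        stream_mask=(stream.data == 1) & valid,
        subwatershed_id=np.where(valid, sub, 0),
        cell_size=landuse.cell_size,
        origin=(landuse.xllcorner, landuse.yllcorner),
        valid=valid,
    )


# ---------------------------------------------------------------------------
# Pre-tabulated zone-area CSV bypass (no geometry required)

_ZONE_CSV_COLUMNS = [
    "subwatershed", "class", "zone", "activity_area_m2", "subwatershed_area_m2",
]


def write_zone_areas_csv(exposures: Sequence[ZoneExposure], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "subwatershed": e.subwatershed,
                "class": e.activity_class,
                "zone": e.zone.label,
                "activity_area_m2": e.activity_area_m2,
                "subwatershed_area_m2": e.subwatershed_area_m2,
            }
            for e in exposures
        ],
        columns=_ZONE_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_zone_areas_csv(path: str | Path) -> list[ZoneExposure]:
    df = pd.read_csv(path)
    missing = [c for c in _ZONE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"zone-area CSV missing columns {missing}")
    return [
        ZoneExposure(
            subwatershed=str(row["subwatershed"]),
            activity_class=row["class"],
            zone=Zone.from_label(str(row["zone"])),
            activity_area_m2=float(row["activity_area_m2"]),
            subwatershed_area_m2=float(row["subwatershed_area_m2"]),
        )
        for _, row in df.iterrows()
    ]
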