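"""Raster/vector data model, ESRI ASCII I/O, and grid conventions.

Conventions used throughout the package:

* row 0 is the northernmost row, indices are 0-based;
* a cell is the half-open box ``[west, east) x (south, north]`` so a point
  exactly on a shared boundary belongs to the cell south-east of it;
* two grids are *aligned* iff shape, origin, cell size and CRS tag are all
  exactly equal, and every cross-layer operation asserts alignment first;
* a cell masked (nodata) in any layer of a stack is masked in the stack's
  land mask;
* geographic distances between points use the haversine formula with Earth
  radius 6371.0088 km; planar grids use Euclidean distance in grid units.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

from .errors import AlignmentError, FormatError, GeometryError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088
#: km per degree of latitude (and of longitude at the equator)
KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0

_ASCII_NODATA = -9999.0


# ---------------------------------------------------------------------------
# RasterGrid
# ---------------------------------------------------------------------------

@dataclass
class RasterGrid:
    """One aligned 2-D layer of values with geotransform and nodata mask.

    Parameters
    ----------
    values
        2-D float array (categorical layers carry integer codes stored as
        floats).
    mask
        Boolean array of the same shape; True marks nodata cells, which are
        excluded from every statistic.
    origin_x, origin_y
        Coordinates of the *top-left corner* of the grid (west edge of
        column 0, north edge of row 0).
    cell_size
        Positive width/height of a square cell, in CRS units.
    crs
        ``"geographic"`` (decimal degrees) or ``"planar"``.
    """

    values: np.ndarray
    mask: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    crs: str = "geographic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise AlignmentError("values and mask shapes differ")
        if self.values.ndim != 2:
            raise FormatError("RasterGrid values must be 2-D")
        if not self.cell_size > 0:
            raise FormatError("cell_size must be positive")
        if self.crs not in ("geographic", "planar"):
            raise FormatError(f"unknown crs tag {self.crs!r}")

    # -- basic geometry -----------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def aligned(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
            and self.cell_size == other.cell_size
            and self.crs == other.crs
        )

    def assert_aligned(self, other: "RasterGrid") -> None:
        if not self.aligned(other):
            raise AlignmentError(
                f"grids not aligned: {self.shape}@({self.origin_x},{self.origin_y})"
                f"x{self.cell_size}/{self.crs} vs "
                f"{other.shape}@({other.origin_x},{other.origin_y})"
                f"x{other.cell_size}/{other.crs}"
            )

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) of cell centres; accepts scalars or arrays."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y - (row + 0.5) * self.cell_size
        return x, y

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """Cell index containing (x, y) under the half-open convention.

        Returns None when the point falls outside the grid extent.
        """
        col = math.floor((x - self.origin_x) / self.cell_size)
        row = math.floor((self.origin_y - y) / self.cell_size)
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    # -- derived grids ------------------------------------------------------

    def like(self, values: np.ndarray, mask: np.ndarray | None = None) -> "RasterGrid":
        """New grid sharing this grid's geometry."""
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            mask=self.mask.copy() if mask is None else np.asarray(mask, dtype=bool),
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            crs=self.crs,
        )

    def land_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def mean(self) -> float:
        """Mean over unmasked cells."""
        return float(self.values[~self.mask].mean())


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII raster (.asc).

    Nodata cells are written as -9999. Values are written with 10
    significant digits, which round-trips float32-level precision.
    """
    path = Path(path)
    vals = np.where(grid.mask, _ASCII_NODATA, grid.values)
    yll = grid.origin_y - grid.n_rows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"NCOLS {grid.n_cols}\n")
        fh.write(f"NROWS {grid.n_rows}\n")
        fh.write(f"XLLCORNER {grid.origin_x!r}\n")
        fh.write(f"YLLCORNER {yll!r}\n")
        fh.write(f"CELLSIZE {grid.cell_size!r}\n")
        fh.write(f"NODATA_VALUE {_ASCII_NODATA:g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_raster(path: str | Path, crs: str = "geographic") -> RasterGrid:
    """Read a single-band raster. Only the ESRI ASCII grid format is
    supported; other extensions raise :class:`FormatError`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raise FormatError(
            "GeoTIFF input is not supported; convert to ESRI ASCII grid (.asc)"
        )
    keys = {"NCOLS", "NROWS", "XLLCORNER", "YLLCORNER", "CELLSIZE", "NODATA_VALUE"}
    try:
        with open(path) as fh:
            header: dict[str, float] = {}
            while True:
                pos = fh.tell()
                parts = fh.readline().split()
                if len(parts) == 2 and parts[0].upper() in keys and _is_number(parts[1]):
                    header[parts[0].upper()] = float(parts[1])
                else:
                    fh.seek(pos)
                    break
            required = {"NCOLS", "NROWS", "XLLCORNER", "YLLCORNER", "CELLSIZE"}
            if not required <= set(header):
                raise FormatError(f"{path}: missing ESRI ASCII header fields")
            data = np.loadtxt(fh, dtype=float)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read raster {path}: {exc}") from exc
    n_rows, n_cols = int(header["NROWS"]), int(header["NCOLS"])
    data = np.atleast_2d(data)
    if data.shape != (n_rows, n_cols):
        raise FormatError(
            f"{path}: data shape {data.shape} != header ({n_rows}, {n_cols})"
        )
    nodata = header.get("NODATA_VALUE", _ASCII_NODATA)
    mask = data == nodata
    origin_y = header["YLLCORNER"] + n_rows * header["CELLSIZE"]
    return RasterGrid(
        values=np.where(mask, 0.0, data),
        mask=mask,
        origin_x=header["XLLCORNER"],
        origin_y=origin_y,
        cell_size=header["CELLSIZE"],
        crs=crs,
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# PredictorStack
# ---------------------------------------------------------------------------

@dataclass
class PredictorStack:
    """Ordered collection of aligned predictor layers.

    ``kinds[i]`` is ``"continuous"`` or ``"categorical"``; categorical
    layers carry integer class codes. The land mask marks a cell usable
    iff it is unmasked in every layer.
    """

    layers: list[RasterGrid]
    names: list[str]
    kinds: list[str]

    def __post_init__(self) -> None:
        if not (len(self.layers) == len(self.names) == len(self.kinds)):
            raise AlignmentError("layers/names/kinds lengths differ")
        if len(set(self.names)) != len(self.names):
            raise AlignmentError("duplicate layer names")
        for kind in self.kinds:
            if kind not in ("continuous", "categorical"):
                raise FormatError(f"unknown layer kind {kind!r}")
        for layer in self.layers[1:]:
            self.layers[0].assert_aligned(layer)

    @property
    def grid(self) -> RasterGrid:
        """Template grid (first layer) defining the stack geometry."""
        return self.layers[0]

    @property
    def land_mask(self) -> np.ndarray:
        """Boolean array, True where the cell is usable in every layer."""
        usable = ~self.layers[0].mask
        for layer in self.layers[1:]:
            usable &= ~layer.mask
        return usable

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def continuous_indices(self) -> list[int]:
        return [i for i, k in enumerate(self.kinds) if k == "continuous"]

    def categorical_indices(self) -> list[int]:
        return [i for i, k in enumerate(self.kinds) if k == "categorical"]

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def values_at(self, cells: Sequence[tuple[int, int]]) -> np.ndarray:
        """Matrix (n_cells x n_layers) of layer values at the given cells."""
        cells = list(cells)
        rows = np.array([c[0] for c in cells], dtype=int)
        cols = np.array([c[1] for c in cells], dtype=int)
        return np.column_stack([lyr.values[rows, cols] for lyr in self.layers])

    def land_cells(self) -> list[tuple[int, int]]:
        rows, cols = np.nonzero(self.land_mask)
        return list(zip(rows.tolist(), cols.tolist()))

    def subset(self, names: Sequence[str]) -> "PredictorStack":
        """Stack restricted to the named layers, preserving stack order."""
        keep = [i for i, n in enumerate(self.names) if n in set(names)]
        return PredictorStack(
            layers=[self.layers[i] for i in keep],
            names=[self.names[i] for i in keep],
            kinds=[self.kinds[i] for i in keep],
        )


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceSet:
    """Presence-only records for one species, reducible to occupied cells."""

    species_id: str
    records: list[tuple[float, float]]
    cells: set[tuple[int, int]] = field(default_factory=set)
    n_dropped: int = 0

    @classmethod
    def from_records(
        cls,
        species_id: str,
        records: Iterable[tuple[float, float]],
        grid: RasterGrid,
        land_mask: np.ndarray | None = None,
    ) -> "OccurrenceSet":
        records = [(float(x), float(y)) for x, y in records]
        cells, dropped = _map_records(records, grid, land_mask)
        return cls(species_id=species_id, records=records, cells=cells, n_dropped=dropped)


def occurrences_to_cells(
    records: Iterable[tuple[float, float]],
    grid: RasterGrid,
    land_mask: np.ndarray | None = None,
) -> set[tuple[int, int]]:
    """Map lon/lat records to the distinct unmasked grid cells containing
    them. Records outside the extent or on masked cells are dropped and the
    count logged."""
    cells, _ = _map_records(list(records), grid, land_mask)
    return cells


def _map_records(records, grid, land_mask):
    if land_mask is None:
        land_mask = ~grid.mask
    cells: set[tuple[int, int]] = set()
    dropped = 0
    for x, y in records:
        cell = grid.cell_of(x, y)
        if cell is None or not land_mask[cell]:
            dropped += 1
            continue
        cells.add(cell)
    if dropped:
        logger.info("dropped %d record(s) outside extent or on masked cells", dropped)
    return cells, dropped


def read_occurrences_csv(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read a `species,lon,lat` CSV into per-species record lists."""
    import pandas as pd

    df = pd.read_csv(path)
    expected = {"species", "lon", "lat"}
    if not expected <= set(df.columns):
        raise FormatError(f"occurrence CSV must have columns {sorted(expected)}")
    out: dict[str, list[tuple[float, float]]] = {}
    for sp, sub in df.groupby("species", sort=True):
        out[str(sp)] = list(zip(sub["lon"].astype(float), sub["lat"].astype(float)))
    return out


def write_occurrences_csv(
    path: str | Path, occurrences: dict[str, list[tuple[float, float]]]
) -> None:
    import pandas as pd

    rows = [
        {"species": sp, "lon": x, "lat": y}
        for sp in sorted(occurrences)
        for x, y in occurrences[sp]
    ]
    pd.DataFrame(rows, columns=["species", "lon", "lat"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Protected areas
# ---------------------------------------------------------------------------

@dataclass
class ProtectedArea:
    """A reserve polygon. Point-like reserves are allowed as degenerate
    small polygons with area below one grid cell."""

    pa_id: str
    vertices: list[tuple[float, float]]
    established_rank: int | None = None

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise GeometryError(f"PA {self.pa_id}: polygon needs >= 3 vertices")

    @property
    def polygon(self) -> Polygon:
        poly = Polygon(self.vertices)
        if poly.area == 0.0 or not poly.is_valid:
            raise GeometryError(f"PA {self.pa_id}: degenerate or invalid polygon")
        return poly

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return c.x, c.y


def point_in_polygon(x: float, y: float, polygon: Sequence[tuple[float, float]]) -> bool:
    """Even-odd membership test; points on the boundary count as inside."""
    if len(polygon) < 3:
        raise GeometryError("polygon needs >= 3 vertices")
    return bool(shapely.covers(Polygon(polygon), Point(x, y)))


def read_pas_geojson(path: str | Path) -> list[ProtectedArea]:
    """Read a GeoJSON FeatureCollection of Polygons with property pa_id."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError("expected a GeoJSON FeatureCollection")
    pas = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise FormatError("only Polygon features are supported")
        ring = [(float(x), float(y)) for x, y in geom["coordinates"][0]]
        props = feat.get("properties", {}) or {}
        pas.append(
            ProtectedArea(
                pa_id=str(props.get("pa_id", f"pa{len(pas)}")),
                vertices=ring,
                established_rank=props.get("established_rank"),
            )
        )
    return pas


def write_pas_geojson(path: str | Path, pas: Sequence[ProtectedArea]) -> None:
    features = []
    for pa in pas:
        ring = list(pa.vertices)
        if ring[0] != ring[-1]:
            ring = ring + [ring[0]]
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "pa_id": pa.pa_id,
                    "established_rank": pa.established_rank,
                },
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def distance_to_polygon_km(
    xs, ys, polygon: Sequence[tuple[float, float]], crs: str = "geographic"
) -> np.ndarray:
    """Minimum distance (km for geographic, grid units for planar) from
    points to a polygon's boundary edges.

    Geographic distances use an equirectangular projection scaled at the
    polygon centroid latitude, accurate to well under 1% at the tens-of-km
    scales used for reserve buffers.
    """
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    ys = np.atleast_1d(np.asarray(ys, dtype=float))
    poly = Polygon(polygon)
    if poly.area == 0.0 and len(polygon) < 3:
        raise GeometryError("degenerate polygon")
    if crs == "geographic":
        lat0 = math.radians(poly.centroid.y)
        kx = KM_PER_DEG * math.cos(lat0)
        ky = KM_PER_DEG
    else:
        kx = ky = 1.0
    verts = np.asarray(polygon, dtype=float)
    ring = shapely.LinearRing(np.column_stack([verts[:, 0] * kx, verts[:, 1] * ky]))
    pts = shapely.points(xs * kx, ys * ky)
    return np.asarray(shapely.distance(ring, pts), dtype=float)
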