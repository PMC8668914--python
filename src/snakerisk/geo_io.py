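"""Reading and writing the formats the pipeline touches.

All geometry inside the package lives in a single projected planar
coordinate system with kilometre units.  Conversion from the metre units
conventionally used in projected files (UTM easting/northing, raster cell
sizes) happens exactly once, at this I/O boundary.  Tables and rasters carry
a unit tag so downstream code can assert the conversion was applied.

Formats:

* point tables       -- CSV (coordinates in metres on disk, km in memory)
* gridded covariates -- ESRI ASCII grid (``.asc``), a plain-text raster
                        format readable by any GIS, with an optional ``.prj``
                        sidecar holding the CRS as WKT
* vector layers      -- GeoJSON, through :mod:`shapely`
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import explain_validity, make_valid

M_PER_KM = 1000.0

__all__ = [
    "PointTable",
    "RasterGrid",
    "read_point_csv",
    "write_point_csv",
    "read_raster",
    "write_raster",
    "read_polygons",
    "write_polygons",
    "read_polylines",
    "write_polylines",
]


class GeoIOError(ValueError):
    """Raised when an input file violates the pipeline's contracts."""


@dataclass
class PointTable:
    """Household point table in km units.

    ``data`` holds one row per household with at least ``hh_id``,
    ``cluster_id``, ``x`` and ``y`` (km) columns; outcome and survey-answer
    columns ride along.  ``n_dropped`` counts rows discarded on read because
    their coordinates could not be parsed.
    """

    data: pd.DataFrame
    unit: str = "km"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.data.empty:
            raise GeoIOError("point table is empty")
        if self.data["hh_id"].duplicated().any():
            raise GeoIOError("hh_id values are not unique")
        xy = self.data[["x", "y"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise GeoIOError("non-finite coordinates in point table")

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of household coordinates in km."""
        return self.data[["x", "y"]].to_numpy(float)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class RasterGrid:
    """Single-band raster on a regular grid, km units.

    ``origin`` is the lower-left *corner* of the grid in km; ``values`` is a
    (n_rows, n_cols) array whose first row is the northernmost (top) row, the
    ESRI ASCII convention.  Cells are half-open: a point exactly on a cell
    edge belongs to the cell to the right of / below it.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0
    unit: str = "km"
    crs_wkt: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GeoIOError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise GeoIOError("raster cell size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in km."""
        x0, y0 = self.origin
        return (
            x0,
            y0,
            x0 + self.n_cols * self.cell_size,
            y0 + self.n_rows * self.cell_size,
        )

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        with np.errstate(invalid="ignore"):
            return ~(np.isclose(self.values, self.nodata) | np.isnan(self.values))

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask()]

    def cell_index(self, x, y):
        """Row/column of the cells containing points ``(x, y)`` (km).

        Half-open convention: a point on a vertical edge falls in the cell to
        its right, a point on a horizontal edge in the cell below it (smaller
        y).  Points outside the footprint get index -1.
        """
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        # edge belongs to the cell below => interval (y0+k*cs, y0+(k+1)*cs]
        k = np.ceil((y - y0) / self.cell_size).astype(int) - 1
        row = self.n_rows - 1 - k
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        col = np.where(inside, col, -1)
        row = np.where(inside, row, -1)
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (n_rows, n_cols) of cell-centre x and y in km."""
        x0, y0 = self.origin
        cs = self.cell_size
        cols = x0 + (np.arange(self.n_cols) + 0.5) * cs
        rows_y = y0 + (self.n_rows - np.arange(self.n_rows) - 0.5) * cs
        return np.meshgrid(cols, rows_y)

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(
            origin=self.origin,
            cell_size=self.cell_size,
            values=np.asarray(values, float),
            nodata=self.nodata,
            unit=self.unit,
            crs_wkt=self.crs_wkt,
        )

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.cell_size, other.cell_size, abs_tol=tol)
            and math.isclose(self.origin[0], other.origin[0], abs_tol=tol)
            and math.isclose(self.origin[1], other.origin[1], abs_tol=tol)
        )


# ---------------------------------------------------------------------------
# point tables


def read_point_csv(
    path,
    column_map: dict[str, str] | None = None,
    outcome_columns: tuple[str, ...] = ("outcome_human",),
) -> PointTable:
    """Read a household table from CSV, converting metres to km.

    ``column_map`` maps internal names (``hh_id``, ``cluster_id``, ``x_m``,
    ``y_m``) to the file's column names.  Rows whose coordinates cannot be
    parsed are dropped and counted in ``n_dropped`` -- survey exports
    routinely contain a handful of unmatched geolocations.
    """
    column_map = column_map or {}
    df = pd.read_csv(path)
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    for required in ("hh_id", "x_m", "y_m"):
        if required not in df.columns:
            raise GeoIOError(f"point CSV is missing required column {required!r}")
    for out in outcome_columns:
        if out not in df.columns:
            raise GeoIOError(f"point CSV is missing outcome column {out!r}")

    x = pd.to_numeric(df["x_m"], errors="coerce")
    y = pd.to_numeric(df["y_m"], errors="coerce")
    good = x.notna() & y.notna()
    n_dropped = int((~good).sum())
    df = df.loc[good].copy()
    if df.empty:
        raise GeoIOError("point CSV contains no usable rows")
    df["x"] = x[good] * (1.0 / M_PER_KM)
    df["y"] = y[good] * (1.0 / M_PER_KM)
    df = df.drop(columns=["x_m", "y_m"]).reset_index(drop=True)
    return PointTable(data=df, unit="km", n_dropped=n_dropped)


def write_point_csv(table: PointTable, path) -> None:
    """Write a point table back to CSV with coordinates in metres."""
    df = table.data.copy()
    df["x_m"] = df.pop("x") * M_PER_KM
    df["y_m"] = df.pop("y") * M_PER_KM
    lead = [c for c in ("hh_id", "cluster_id", "x_m", "y_m") if c in df.columns]
    df = df[lead + [c for c in df.columns if c not in lead]]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rasters (ESRI ASCII grid)


def _looks_geographic(wkt: str) -> bool:
    w = wkt.upper()
    return ("GEOGCS" in w or "GEOGCRS" in w) and ("PROJCS" not in w and "PROJCRS" not in w)


def read_raster(path) -> RasterGrid:
    """Read a single-band ESRI ASCII grid; on-disk metres become km.

    A ``.prj`` sidecar (WKT) is consulted when present; a geographic
    (degree-unit) CRS is rejected -- project the raster to a planar CRS such
    as WGS 84 / UTM first.
    """
    path = Path(path)
    header: dict[str, float] = {}
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GeoIOError(f"ASCII grid {path} is missing header field {key!r}")

    prj = path.with_suffix(".prj")
    crs_wkt = prj.read_text().strip() if prj.exists() else None
    if crs_wkt is not None and _looks_geographic(crs_wkt):
        raise GeoIOError(
            f"raster {path} is in a geographic (degree) CRS; project it to a "
            "planar CRS (e.g. WGS 84 / UTM zone 45N) before use"
        )

    values = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise GeoIOError(f"ASCII grid {path}: data shape does not match header")
    return RasterGrid(
        origin=(header["xllcorner"] / M_PER_KM, header["yllcorner"] / M_PER_KM),
        cell_size=header["cellsize"] / M_PER_KM,
        values=values,
        nodata=header.get("nodata_value", -9999.0),
        unit="km",
        crs_wkt=crs_wkt,
    )


def write_raster(grid: RasterGrid, path) -> None:
    """Write a raster as an ESRI ASCII grid (metres on disk)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {float(grid.origin[0]) * M_PER_KM:.17g}\n")
        fh.write(f"yllcorner {float(grid.origin[1]) * M_PER_KM:.17g}\n")
        fh.write(f"cellsize {float(grid.cell_size) * M_PER_KM:.17g}\n")
        fh.write(f"nodata_value {float(grid.nodata):.17g}\n")
        for row in grid.values:
            fh.write(" ".join(f"{float(v):.17g}" for v in row) + "\n")
    if grid.crs_wkt:
        path.with_suffix(".prj").write_text(grid.crs_wkt)


# ---------------------------------------------------------------------------
# vector layers (GeoJSON)


def _load_geojson(path) -> list[dict]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise GeoIOError(f"{path}: expected a GeoJSON FeatureCollection")
    return gj["features"]


def _repair(geom: BaseGeometry, repair: bool, what: str) -> BaseGeometry:
    if geom.is_valid:
        return geom
    if not repair:
        raise GeoIOError(f"invalid {what}: {explain_validity(geom)}")
    warnings.warn(f"repaired invalid {what}: {explain_validity(geom)}", stacklevel=3)
    return make_valid(geom)


def read_polygons(path, id_property: str = "unit_id", repair: bool = True):
    """Read admin/exclusion polygons; returns ``{unit_id: shapely geometry}``.

    Coordinates on disk are metres (projected CRS); returned geometries are
    in km.  Self-intersecting rings are repaired (default) or rejected.
    """
    units: dict = {}
    for feat in _load_geojson(path):
        props = feat.get("properties") or {}
        if id_property not in props:
            raise GeoIOError(f"polygon feature missing {id_property!r} property")
        uid = props[id_property]
        if uid in units:
            raise GeoIOError(f"duplicate unit id {uid!r} in {path}")
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise GeoIOError(f"feature {uid!r} is not a polygon")
        geom = _repair(geom, repair, f"polygon {uid!r}")
        units[uid] = _scale_geom(geom, 1.0 / M_PER_KM)
    if not units:
        raise GeoIOError(f"no polygon features in {path}")
    return units


def read_polylines(path, repair: bool = True):
    """Read water (or other) polylines/polygons as a list of km geometries."""
    geoms = []
    for feat in _load_geojson(path):
        geom = shape(feat["geometry"])
        geom = _repair(geom, repair, geom.geom_type)
        geoms.append(_scale_geom(geom, 1.0 / M_PER_KM))
    if not geoms:
        raise GeoIOError(f"no features in {path}")
    return geoms


def _scale_geom(geom: BaseGeometry, factor: float) -> BaseGeometry:
    from shapely import affinity

    return affinity.scale(geom, xfact=factor, yfact=factor, origin=(0, 0))


def write_polygons(units: dict, path, id_property: str = "unit_id") -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {id_property: uid},
            "geometry": mapping(_scale_geom(geom, M_PER_KM)),
        }
        for uid, geom in units.items()
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def write_polylines(geoms, path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {},
            "geometry": mapping(_scale_geom(geom, M_PER_KM)),
        }
        for geom in geoms
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
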