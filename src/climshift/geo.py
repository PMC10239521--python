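"""Geodesy, compass-angle conventions and equal-area hexagon tessellation.

All spatial quantities in the package flow through this module: displacement
components in km between lat/lon points, shift vectors in compass convention
(0 deg = north, clockwise), and the equal-area hexagon grid onto which gridded
temperatures are aggregated.

Distances use a local equirectangular approximation on a sphere of mean radius
R = 6371.0088 km.  Displacements in this study are regional (well under
1500 km at 55-70 deg N), where the approximation agrees with great-circle
distances to a small fraction of a percent; it is also exactly invertible,
which the hexagon lattice construction relies on.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon, box, mapping, shape
from shapely.strtree import STRtree

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "ShiftVector",
    "HexGrid",
    "ProvinceMap",
    "EqualAreaProjection",
    "northward_eastward_components",
    "vector_from_points",
    "compass_from_components",
    "build_hexgrid",
]


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 latitude/longitude point in degrees."""

    lat: float
    lon: float

    def __post_init__(self):
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise ValueError("GeoPoint coordinates must be finite")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class ShiftVector:
    """A displacement on the landscape over a period of years.

    Direction is compass convention: 0 deg = due north, increasing clockwise,
    stored in [0, 360).  A zero-magnitude vector has no defined direction;
    ``direction_defined`` is then False and ``direction_deg`` is NaN.
    """

    origin: GeoPoint
    east_km: float
    north_km: float
    period: tuple[int, int]
    magnitude_km: float = field(init=False)
    direction_deg: float = field(init=False)
    direction_defined: bool = field(init=False)

    def __post_init__(self):
        start, end = self.period
        if not start < end:
            raise ValueError(f"period {self.period} must satisfy start < end")
        mag = math.hypot(self.east_km, self.north_km)
        object.__setattr__(self, "magnitude_km", mag)
        if mag == 0.0:
            object.__setattr__(self, "direction_deg", float("nan"))
            object.__setattr__(self, "direction_defined", False)
        else:
            object.__setattr__(
                self, "direction_deg", compass_from_components(self.east_km, self.north_km)
            )
            object.__setattr__(self, "direction_defined", True)

    @property
    def years(self) -> int:
        return self.period[1] - self.period[0]


def compass_from_components(east_km: float, north_km: float) -> float:
    """Compass bearing in [0, 360) of an (east, north) displacement."""
    deg = math.degrees(math.atan2(east_km, north_km)) % 360.0
    return 0.0 if deg >= 360.0 else deg


def northward_eastward_components(a: GeoPoint, b: GeoPoint) -> tuple[float, float]:
    """Signed (north_km, east_km) displacement from ``a`` to ``b``.

    Local equirectangular convention: north = R * dlat, east scaled by the
    cosine of the mean latitude.  Antisymmetric under swapping the endpoints.
    """
    north = EARTH_RADIUS_KM * math.radians(b.lat - a.lat)
    mean_lat = math.radians(0.5 * (a.lat + b.lat))
    east = EARTH_RADIUS_KM * math.cos(mean_lat) * math.radians(b.lon - a.lon)
    return north, east


def vector_from_points(a: GeoPoint, b: GeoPoint, period: tuple[int, int]) -> ShiftVector:
    """ShiftVector for the displacement a -> b over ``period``."""
    north, east = northward_eastward_components(a, b)
    return ShiftVector(origin=a, east_km=east, north_km=north, period=period)


class EqualAreaProjection:
    """Lambert cylindrical equal-area projection with a local standard parallel.

    x = R * cos(phi_s) * (lon - lon0),  y = R * sin(lat) / cos(phi_s),
    both in km.  Exactly area-preserving, so a hexagon drawn with area A in
    the projected plane has area A on the sphere.
    """

    def __init__(self, lat0: float, lon0: float):
        self.lat0 = float(lat0)
        self.lon0 = float(lon0)
        self._cos0 = math.cos(math.radians(lat0))

    def forward(self, lat, lon):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        x = EARTH_RADIUS_KM * self._cos0 * np.radians(lon - self.lon0)
        y = EARTH_RADIUS_KM * np.sin(np.radians(lat)) / self._cos0
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon = self.lon0 + np.degrees(x / (EARTH_RADIUS_KM * self._cos0))
        s = np.clip(y * self._cos0 / EARTH_RADIUS_KM, -1.0, 1.0)
        lat = np.degrees(np.arcsin(s))
        return lat, lon

    def project_polygon(self, poly_lonlat: Polygon) -> Polygon:
        lon, lat = np.asarray(poly_lonlat.exterior.coords).T
        x, y = self.forward(lat, lon)
        return Polygon(np.column_stack([x, y]))

    def unproject_polygon(self, poly_xy: Polygon) -> Polygon:
        x, y = np.asarray(poly_xy.exterior.coords).T
        lat, lon = self.inverse(x, y)
        return Polygon(np.column_stack([lon, lat]))


@dataclass
class HexGrid:
    """Equal-area hexagon tessellation of a lat/lon bounding box.

    ``cell_ids`` are dense integers; centroids are the hexagon lattice centres
    (in lat/lon); ``polygons_lonlat`` are the cells clipped to the bbox.
    ``interior`` flags cells whose full hexagon lies inside the bbox, i.e.
    whose realised area equals ``cell_area_km2``.
    """

    cell_ids: np.ndarray
    centroid_lat: np.ndarray
    centroid_lon: np.ndarray
    polygons_lonlat: list[Polygon]
    cell_area_km2: float
    interior: np.ndarray
    projection: EqualAreaProjection

    def __len__(self) -> int:
        return len(self.cell_ids)

    def centroid(self, cell_id: int) -> GeoPoint:
        i = int(np.searchsorted(self.cell_ids, cell_id))
        return GeoPoint(float(self.centroid_lat[i]), float(self.centroid_lon[i]))

    def cell_containing(self, point: GeoPoint) -> int | None:
        """cell_id of the clipped cell containing ``point``, else nearest centroid cell."""
        if not hasattr(self, "_tree"):
            self._tree = STRtree(self.polygons_lonlat)
        p = Point(point.lon, point.lat)
        for i in self._tree.query(p):
            if self.polygons_lonlat[int(i)].covers(p):
                return int(self.cell_ids[int(i)])
        d2 = (self.centroid_lat - point.lat) ** 2 + (self.centroid_lon - point.lon) ** 2
        return int(self.cell_ids[int(np.argmin(d2))])

    def to_geojson(self) -> dict:
        feats = []
        for i, poly in enumerate(self.polygons_lonlat):
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(poly),
                    "properties": {
                        "cell_id": int(self.cell_ids[i]),
                        "centroid_lat": float(self.centroid_lat[i]),
                        "centroid_lon": float(self.centroid_lon[i]),
                        "interior": bool(self.interior[i]),
                    },
                }
            )
        return {"type": "FeatureCollection", "features": feats}


def build_hexgrid(
    bbox: tuple[float, float, float, float], cell_area_km2: float = 2165.0
) -> HexGrid:
    """Tile a (lat_min, lat_max, lon_min, lon_max) box with flat-topped hexagons.

    The lattice is constructed in a cylindrical equal-area projection centred
    on the box, so every full hexagon has area ``cell_area_km2`` on the sphere
    (default 2165 km^2).  Cells are clipped to the box; the box is covered
    completely and without overlap.
    """
    lat_min, lat_max, lon_min, lon_max = map(float, bbox)
    if not (lat_min < lat_max and lon_min < lon_max):
        raise ValueError("bbox must be non-degenerate (lat_min < lat_max, lon_min < lon_max)")
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")

    proj = EqualAreaProjection(0.5 * (lat_min + lat_max), 0.5 * (lon_min + lon_max))
    # project bbox corners; in this projection the box maps to a rectangle
    x0, y0 = proj.forward(lat_min, lon_min)
    x1, y1 = proj.forward(lat_max, lon_max)
    x0, y0, x1, y1 = float(x0), float(y0), float(x1), float(y1)
    bbox_poly = box(x0, y0, x1, y1)

    if cell_area_km2 >= bbox_poly.area:
        warnings.warn("bbox smaller than one cell; returning a single-cell grid")

    # flat-topped regular hexagon with area A: side s, column pitch 1.5 s,
    # row pitch sqrt(3) s; adjacent centre spacing sqrt(2A/sqrt(3))
    s = math.sqrt(2.0 * cell_area_km2 / (3.0 * math.sqrt(3.0)))
    dx, dy = 1.5 * s, math.sqrt(3.0) * s

    nx = int(math.ceil((x1 - x0) / dx)) + 2
    ny = int(math.ceil((y1 - y0) / dy)) + 2

    hex_corners = np.array(
        [(s * math.cos(a), s * math.sin(a)) for a in np.arange(6) * (math.pi / 3.0)]
    )

    cells = []
    for i in range(-1, nx):
        cx = x0 + i * dx
        for j in range(-1, ny):
            cy = y0 + j * dy + (0.5 * dy if i % 2 else 0.0)
            hexagon = Polygon(hex_corners + (cx, cy))
            if not hexagon.intersects(bbox_poly):
                continue
            clipped = hexagon.intersection(bbox_poly)
            if clipped.is_empty or clipped.area < 1e-9:
                continue
            interior = hexagon.within(bbox_poly.buffer(1e-9))
            cells.append((cx, cy, clipped, interior))

    cells.sort(key=lambda c: (c[1], c[0]))  # deterministic row-major ids

    # absorb boundary slivers (clipped area < A/2) into the neighbouring kept
    # cell sharing the longest border, so the realised cell count tracks
    # bbox area / cell area and no cell is a degenerate fragment
    kept = [c for c in cells if c[2].area >= 0.5 * cell_area_km2]
    slivers = [c for c in cells if c[2].area < 0.5 * cell_area_km2]
    if kept and slivers:
        merged = {i: c[2] for i, c in enumerate(kept)}
        absorbed = set()
        for s in slivers:
            shared = [
                (merged[i].intersection(s[2]).length, -i) for i in merged
                if merged[i].distance(s[2]) < 1e-9
            ]
            if not shared:
                continue
            _, neg_i = max(shared)
            i = -neg_i
            merged[i] = merged[i].union(s[2])
            absorbed.add(i)
        cells = [
            (c[0], c[1], merged[i], c[3] and i not in absorbed)
            for i, c in enumerate(kept)
        ]
    ids = np.arange(len(cells))
    cx = np.array([c[0] for c in cells])
    cy = np.array([c[1] for c in cells])
    lat, lon = proj.inverse(cx, cy)
    polys = [proj.unproject_polygon(c[2]) if isinstance(c[2], Polygon) else
             proj.unproject_polygon(max(c[2].geoms, key=lambda g: g.area)) for c in cells]
    interior = np.array([c[3] for c in cells], dtype=bool)
    return HexGrid(
        cell_ids=ids,
        centroid_lat=np.asarray(lat),
        centroid_lon=np.asarray(lon),
        polygons_lonlat=polys,
        cell_area_km2=cell_area_km2,
        interior=interior,
        projection=proj,
    )


@dataclass
class ProvinceMap:
    """Province polygons with centroids and areas; the spatial frame of the study.

    Polygons are WGS84 lon/lat; areas are computed in a cylindrical equal-area
    projection centred on the map, in km^2.
    """

    province_ids: list[str]
    polygons: list[Polygon]
    names: list[str] | None = None
    countries: list[str] | None = None

    def __post_init__(self):
        if len(set(self.province_ids)) != len(self.province_ids):
            raise ValueError("province ids must be unique")
        lats = [p.centroid.y for p in self.polygons]
        lons = [p.centroid.x for p in self.polygons]
        self._proj = EqualAreaProjection(float(np.mean(lats)), float(np.mean(lons)))
        self._index = {pid: i for i, pid in enumerate(self.province_ids)}

    def __len__(self) -> int:
        return len(self.province_ids)

    def centroid(self, province_id: str) -> GeoPoint:
        c = self.polygons[self._index[province_id]].centroid
        return GeoPoint(c.y, c.x)

    def centroids(self) -> dict[str, GeoPoint]:
        return {pid: self.centroid(pid) for pid in self.province_ids}

    def area_km2(self, province_id: str) -> float:
        poly = self.polygons[self._index[province_id]]
        return self._proj.project_polygon(poly).area

    def areas_km2(self) -> dict[str, float]:
        return {pid: self.area_km2(pid) for pid in self.province_ids}

    def contains(self, province_id: str, point: GeoPoint) -> bool:
        return self.polygons[self._index[province_id]].covers(Point(point.lon, point.lat))

    def province_of_cells(self, grid: HexGrid) -> dict[int, str | None]:
        """Assign hexagon cells to provinces by centroid-in-polygon containment."""
        tree = STRtree(self.polygons)
        out: dict[int, str | None] = {}
        for cid, lat, lon in zip(grid.cell_ids, grid.centroid_lat, grid.centroid_lon):
            p = Point(lon, lat)
            hit = None
            for j in tree.query(p):
                if self.polygons[int(j)].covers(p):
                    hit = self.province_ids[int(j)]
                    break
            out[int(cid)] = hit
        return out

    def adjacency(self) -> dict[str, set[str]]:
        """Provinces sharing a border segment (positive-length intersection)."""
        adj: dict[str, set[str]] = {pid: set() for pid in self.province_ids}
        tree = STRtree(self.polygons)
        for i, poly in enumerate(self.polygons):
            for j in tree.query(poly):
                j = int(j)
                if j <= i:
                    continue
                inter = poly.intersection(self.polygons[j])
                if inter.length > 1e-9:
                    adj[self.province_ids[i]].add(self.province_ids[j])
                    adj[self.province_ids[j]].add(self.province_ids[i])
        return adj

    def to_geojson(self) -> dict:
        feats = []
        for i, pid in enumerate(self.province_ids):
            props = {"province_id": pid}
            if self.names:
                props["name"] = self.names[i]
            if self.countries:
                props["country"] = self.countries[i]
            feats.append(
                {"type": "Feature", "geometry": mapping(self.polygons[i]), "properties": props}
            )
        return {"type": "FeatureCollection", "features": feats}

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)

    @classmethod
    def from_geojson(cls, gj: dict) -> "ProvinceMap":
        ids, polys, names, countries = [], [], [], []
        for feat in gj["features"]:
            props = feat.get("properties", {})
            ids.append(str(props["province_id"]))
            names.append(props.get("name", ""))
            countries.append(props.get("country", ""))
            geom = shape(feat["geometry"])
            if geom.geom_type == "MultiPolygon":
                geom = max(geom.geoms, key=lambda g: g.area)
            polys.append(geom)
        return cls(province_ids=ids, polygons=polys, names=names, countries=countries)

    @classmethod
    def from_file(cls, path) -> "ProvinceMap":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))
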