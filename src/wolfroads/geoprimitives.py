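"""Planar geometry kernel for the road-ecology pipeline.

All coordinates are planar meters (a projected CRS is assumed upstream);
no geographic math is performed anywhere. Internal areas are m**2 and are
reported in km**2; line densities in km/km**2.

The workhorse objects are a polyline road network with a per-line class
(``gravel`` or ``main``), a point layer for houses, a categorical land-cover
grid (Forest / Mire / Water / Open), and convex polygons used as 100% minimum
convex polygon (MCP) home ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError, cKDTree
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union
from shapely.strtree import STRtree

ROAD_CLASSES = ("gravel", "main")
LANDCOVER_CLASSES = ("Forest", "Mire", "Water", "Open")
_CLASS_TO_CODE = {c: i for i, c in enumerate(LANDCOVER_CLASSES)}


class NoFeatureError(ValueError):
    """The (filtered) feature layer is empty."""


class OutOfExtentError(ValueError):
    """A query point lies outside the land-cover grid extent."""


class DegenerateRegionError(ValueError):
    """A region has zero land area."""


class DegenerateHullError(ValueError):
    """Fewer than three non-collinear points: no convex hull exists."""


@dataclass(frozen=True)
class PointXY:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def _as_xy(p) -> np.ndarray:
    if isinstance(p, PointXY):
        return p.as_array()
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"expected a 2-vector, got shape {a.shape}")
    return a


# ---------------------------------------------------------------------------
# Road network
# ---------------------------------------------------------------------------


@dataclass
class RoadNetwork:
    """Polyline network with a road class per polyline.

    ``lines[i]`` is an (k_i, 2) float array of vertices (k_i >= 2);
    ``classes[i]`` is ``"gravel"`` or ``"main"``.
    """

    lines: list[np.ndarray]
    classes: list[str]
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.lines) != len(self.classes):
            raise ValueError("lines and classes must have equal length")
        self.lines = [np.asarray(l, dtype=float) for l in self.lines]
        for l in self.lines:
            if l.ndim != 2 or l.shape[0] < 2 or l.shape[1] != 2:
                raise ValueError("every polyline needs >=2 vertices of (x, y)")
        for c in self.classes:
            if c not in ROAD_CLASSES:
                raise ValueError(f"unknown road class {c!r}")

    def subset(self, road_class: str | None) -> "RoadNetwork":
        if road_class is None:
            return self
        key = ("__subset__", road_class)
        if key not in self._trees:
            keep = [i for i, c in enumerate(self.classes) if c == road_class]
            self._trees[key] = RoadNetwork(
                [self.lines[i] for i in keep], [self.classes[i] for i in keep]
            )
        return self._trees[key]

    def is_empty(self) -> bool:
        return len(self.lines) == 0

    def total_length(self, road_class: str | None = None) -> float:
        """Summed polyline length in meters."""
        net = self.subset(road_class)
        return float(
            sum(np.sum(np.hypot(*np.diff(l, axis=0).T)) for l in net.lines)
        )

    def segments(self, road_class: str | None = None) -> np.ndarray:
        """All line segments as an (m, 2, 2) array (cached per class)."""
        key = ("__segs__", road_class)
        if key not in self._trees:
            net = self.subset(road_class)
            parts = [np.stack([l[:-1], l[1:]], axis=1) for l in net.lines]
            self._trees[key] = (
                np.concatenate(parts) if parts else np.empty((0, 2, 2))
            )
        return self._trees[key]

    def shapely_lines(self, road_class: str | None = None) -> list[LineString]:
        return [LineString(l) for l in self.subset(road_class).lines]

    def merged(self, road_class: str | None = None):
        return unary_union(self.shapely_lines(road_class))

    def corridor(self, width: float, road_class: str | None = None):
        """Union of per-polyline buffers (the exact dissolved road corridor);
        cached per (width, class)."""
        key = ("__corridor__", width, road_class)
        if key not in self._trees:
            lines = self.shapely_lines(road_class)
            if not lines:
                self._trees[key] = Polygon()
            else:
                self._trees[key] = shapely.union_all(
                    shapely.buffer(np.array(lines, dtype=object), width)
                )
        return self._trees[key]

    def _tree(self, road_class: str | None):
        key = road_class or "__all__"
        if key not in self._trees:
            geoms = self.shapely_lines(road_class)
            self._trees[key] = STRtree(geoms) if geoms else None
        return self._trees[key]

    # -- GeoJSON round trip -------------------------------------------------

    def to_geojson(self) -> dict:
        feats = [
            {
                "type": "Feature",
                "properties": {"class": c},
                "geometry": {"type": "LineString", "coordinates": l.tolist()},
            }
            for l, c in zip(self.lines, self.classes)
        ]
        return {"type": "FeatureCollection", "features": feats}

    @classmethod
    def from_geojson(cls, obj: dict) -> "RoadNetwork":
        lines, classes = [], []
        for feat in obj["features"]:
            geom = feat["geometry"]
            cls_name = feat.get("properties", {}).get("class", "gravel")
            if geom["type"] == "LineString":
                coords = [geom["coordinates"]]
            elif geom["type"] == "MultiLineString":
                coords = geom["coordinates"]
            else:
                raise ValueError(f"unsupported geometry {geom['type']}")
            for cc in coords:
                lines.append(np.asarray(cc, dtype=float))
                classes.append(cls_name)
        return cls(lines, classes)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)

    @classmethod
    def load(cls, path) -> "RoadNetwork":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))


def distance_to_network(p, net: RoadNetwork, class_filter: str | None = None) -> float:
    """Minimum Euclidean distance (m) from a point to the (filtered) network."""
    return float(distances_to_network(_as_xy(p)[None, :], net, class_filter)[0])


def distances_to_network(
    points: np.ndarray, net: RoadNetwork, class_filter: str | None = None
) -> np.ndarray:
    """Vectorized nearest-feature distance (m) for an (n, 2) point array."""
    tree = net._tree(class_filter)
    if tree is None:
        raise NoFeatureError(f"no features of class {class_filter!r}")
    pts = shapely.points(np.asarray(points, dtype=float))
    _, dist = tree.query_nearest(pts, return_distance=True, all_matches=False)
    return np.asarray(dist, dtype=float)


def _segment_circle_params(seg: np.ndarray, center: np.ndarray, radius: float):
    """Parameter interval [t0, t1] of seg inside the circle, or None."""
    p, q = seg
    d = q - p
    f = p - center
    a = d @ d
    if a == 0.0:
        return (0.0, 1.0) if f @ f <= radius * radius else None
    b = f @ d
    c = f @ f - radius * radius
    disc = b * b - a * c
    if disc < 0:
        return None
    sq = np.sqrt(disc)
    t0 = max((-b - sq) / a, 0.0)
    t1 = min((-b + sq) / a, 1.0)
    if t1 <= t0:
        return None
    return (t0, t1)


def line_length_in_circle(net: RoadNetwork, center, radius: float) -> float:
    """Total network length inside a circle, in km (exact segment clipping)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    c = _as_xy(center)
    segs = net.segments()
    if segs.shape[0] == 0:
        return 0.0
    # vectorized quadratic solve over all segments
    p = segs[:, 0, :]
    d = segs[:, 1, :] - p
    f = p - c
    a = np.einsum("ij,ij->i", d, d)
    b = np.einsum("ij,ij->i", f, d)
    cc = np.einsum("ij,ij->i", f, f) - radius * radius
    length = np.sqrt(a)
    total = 0.0
    disc = b * b - a * cc
    ok = (disc >= 0) & (a > 0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = np.clip((-b - sq) / a, 0.0, 1.0)
        t1 = np.clip((-b + sq) / a, 0.0, 1.0)
    span = np.where(ok, np.maximum(t1 - t0, 0.0), 0.0)
    # degenerate zero-length segments contribute nothing
    total = float(np.sum(span * length))
    return total / 1000.0


# ---------------------------------------------------------------------------
# Land cover grid
# ---------------------------------------------------------------------------


@dataclass
class LandCoverGrid:
    """Categorical raster with square cells.

    ``codes[i, j]`` covers x in [x0 + j*cs, x0 + (j+1)*cs) and
    y in [y0 + i*cs, y0 + (i+1)*cs). Codes index ``LANDCOVER_CLASSES``.
    """

    origin: tuple[float, float]
    cell_size: float
    codes: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D")
        if self.codes.min() < 0 or self.codes.max() >= len(LANDCOVER_CLASSES):
            raise ValueError("codes out of range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin
        ny, nx = self.codes.shape
        return (x0, y0, x0 + nx * self.cell_size, y0 + ny * self.cell_size)

    def contains(self, p) -> bool:
        x, y = _as_xy(p)
        x0, y0, x1, y1 = self.extent
        return x0 <= x < x1 and y0 <= y < y1

    def cell_index(self, p) -> tuple[int, int]:
        x, y = _as_xy(p)
        if not self.contains(p):
            raise OutOfExtentError(f"point ({x}, {y}) outside grid extent {self.extent}")
        x0, y0 = self.origin
        j = int((x - x0) // self.cell_size)
        i = int((y - y0) // self.cell_size)
        return i, j

    def class_fractions(self) -> dict[str, float]:
        n = self.codes.size
        return {
            c: float(np.sum(self.codes == k)) / n
            for k, c in enumerate(LANDCOVER_CLASSES)
        }

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(centers (n,2), codes (n,)) for all cells."""
        if "centers" not in self._cache:
            x0, y0 = self.origin
            ny, nx = self.codes.shape
            xs = x0 + (np.arange(nx) + 0.5) * self.cell_size
            ys = y0 + (np.arange(ny) + 0.5) * self.cell_size
            xx, yy = np.meshgrid(xs, ys)
            self._cache["centers"] = (
                np.column_stack([xx.ravel(), yy.ravel()]),
                self.codes.ravel(),
            )
        return self._cache["centers"]

    def _land_tree(self) -> cKDTree:
        if "land_tree" not in self._cache:
            centers, codes = self.cell_centers()
            land = codes != _CLASS_TO_CODE["Water"]
            if not np.any(land):
                raise NoFeatureError("grid has no terrestrial cells")
            self._cache["land_tree"] = (cKDTree(centers[land]), codes[land])
        return self._cache["land_tree"]

    def water_union(self) -> Polygon:
        """Union of all Water cells as a (multi)polygon; cached."""
        if "water_union" not in self._cache:
            centers, codes = self.cell_centers()
            w = centers[codes == _CLASS_TO_CODE["Water"]]
            h = self.cell_size / 2.0
            boxes = [shapely.box(x - h, y - h, x + h, y + h) for x, y in w]
            self._cache["water_union"] = unary_union(boxes) if boxes else Polygon()
        return self._cache["water_union"]

    # -- ASCII grid I/O -----------------------------------------------------

    def to_ascii(self, path) -> None:
        x0, y0 = self.origin
        ny, nx = self.codes.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {nx}\nnrows {ny}\n")
            fh.write(f"xllcorner {x0}\nyllcorner {y0}\ncellsize {self.cell_size}\n")
            # rows written top-down as in ESRI ASCII grids
            for row in self.codes[::-1]:
                fh.write(" ".join(map(str, row.tolist())) + "\n")

    @classmethod
    def from_ascii(cls, path) -> "LandCoverGrid":
        with open(path) as fh:
            hdr = {}
            for _ in range(5):
                k, v = fh.readline().split()
                hdr[k.lower()] = float(v)
            codes = np.loadtxt(fh, dtype=np.int8)
        codes = np.atleast_2d(codes)[::-1]
        return cls(
            (hdr["xllcorner"], hdr["yllcorner"]), hdr["cellsize"], codes
        )


def landcover_at(p, grid: LandCoverGrid, terrestrial_fallback: bool = False) -> str:
    """Land-cover class at a point; optionally snap Water to nearest land cell."""
    i, j = grid.cell_index(p)
    code = int(grid.codes[i, j])
    cls = LANDCOVER_CLASSES[code]
    if cls == "Water" and terrestrial_fallback:
        tree, codes = grid._land_tree()
        _, idx = tree.query(_as_xy(p))
        cls = LANDCOVER_CLASSES[int(codes[idx])]
    return cls


def landcover_at_many(
    points: np.ndarray, grid: LandCoverGrid, terrestrial_fallback: bool = False
) -> np.ndarray:
    """Vectorized `landcover_at` for an (n, 2) array; raises if any point is outside."""
    pts = np.asarray(points, dtype=float)
    x0, y0, x1, y1 = grid.extent
    if np.any((pts[:, 0] < x0) | (pts[:, 0] >= x1) | (pts[:, 1] < y0) | (pts[:, 1] >= y1)):
        raise OutOfExtentError("some points fall outside the grid extent")
    jj = ((pts[:, 0] - x0) // grid.cell_size).astype(int)
    ii = ((pts[:, 1] - y0) // grid.cell_size).astype(int)
    codes = grid.codes[ii, jj].astype(int)
    if terrestrial_fallback:
        wet = codes == _CLASS_TO_CODE["Water"]
        if np.any(wet):
            tree, land_codes = grid._land_tree()
            _, idx = tree.query(pts[wet])
            codes[wet] = land_codes[np.atleast_1d(idx)]
    return np.array([LANDCOVER_CLASSES[c] for c in codes])


# ---------------------------------------------------------------------------
# Convex polygons / MCP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConvexPolygon:
    """Convex ring (counter-clockwise, first vertex not repeated)."""

    vertices: np.ndarray

    @property
    def area_m2(self) -> float:
        v = self.vertices
        x, y = v[:, 0], v[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    @property
    def area_km2(self) -> float:
        return self.area_m2 / 1e6

    def shapely(self) -> Polygon:
        return Polygon(self.vertices)

    def contains(self, p, atol: float = 1e-9) -> bool:
        """Point-in-convex-polygon, boundary inclusive."""
        return bool(self.contains_many(_as_xy(p)[None, :], atol)[0])

    def contains_many(self, points: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        v = self.vertices
        w = np.roll(v, -1, axis=0)
        edge = w - v
        # cross((w - v), (p - v)) >= 0 for all edges of a CCW ring
        rel = pts[:, None, :] - v[None, :, :]
        cross = edge[None, :, 0] * rel[:, :, 1] - edge[None, :, 1] * rel[:, :, 0]
        scale = np.hypot(edge[:, 0], edge[:, 1])[None, :]
        return np.all(cross >= -atol * np.maximum(scale, 1.0), axis=1)

    def to_geojson(self) -> dict:
        ring = np.vstack([self.vertices, self.vertices[:1]]).tolist()
        return {
            "type": "Feature",
            "properties": {"area_km2": self.area_km2},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        }


def mcp(points: Iterable) -> ConvexPolygon:
    """100% minimum convex polygon (convex hull) of a point set.

    Raises `DegenerateHullError` for <3 points or a collinear set.
    """
    pts = np.asarray(
        [_as_xy(p) for p in points] if not isinstance(points, np.ndarray) else points,
        dtype=float,
    )
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise DegenerateHullError("need at least 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateHullError("points are collinear") from exc
    return ConvexPolygon(pts[hull.vertices])  # scipy returns CCW order in 2-D


def buffered_network_land_fraction(
    net: RoadNetwork,
    region: ConvexPolygon | Polygon,
    grid: LandCoverGrid,
    width: float,
) -> float:
    """Fraction of a region's land (non-Water) area within `width` m of the network.

    The buffered corridor is the exact union of round-capped segment buffers
    (shapely polygon union: rectangles plus junction disks, no double
    counting), intersected with the region and with land.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    poly = region.shapely() if isinstance(region, ConvexPolygon) else region
    water = grid.water_union()
    land_area = poly.area - poly.intersection(water).area
    if land_area <= 0:
        raise DegenerateRegionError("region has zero land area")
    if net.is_empty():
        return 0.0
    corridor = net.corridor(width)
    clipped = corridor.intersection(poly)
    corridor_land = clipped.area - clipped.intersection(water).area
    return float(corridor_land / land_area)


# ---------------------------------------------------------------------------
# Small helpers shared by the analysis modules
# ---------------------------------------------------------------------------


def points_in_circle_count(points: np.ndarray, center, radius: float) -> int:
    if len(points) == 0:
        return 0
    pts = np.asarray(points, dtype=float)
    c = _as_xy(center)
    return int(np.sum(np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) <= radius))


def save_points_geojson(points: np.ndarray, path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {},
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
        }
        for x, y in np.asarray(points, dtype=float)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def load_points_geojson(path) -> np.ndarray:
    with open(path) as fh:
        obj = json.load(fh)
    pts = [f["geometry"]["coordinates"] for f in obj["features"]]
    return np.asarray(pts, dtype=float) if pts else np.empty((0, 2))
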