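"""Grid data model and raster/vector primitives.

All layers live on a shared projected planar grid (metres). Row 0 is the
northern edge; cell (r, c) has its center at
``(origin_x + (c + 0.5) * cell_size, origin_y - (r + 0.5) * cell_size)``.
Missing data is represented by NaN and is a distinct state, never conflated
with 0: any missing input at a cell makes derived cells missing, so absent
data can never count as suitable or unsuitable.

Rasters are read and written as ESRI ASCII grids (plain text), vector data
as GeoJSON or CSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, mapping, shape


class GridError(ValueError):
    """Raised for invalid grid specifications or mismatched grids."""


class DisjointExtentError(GridError):
    """Raised when two layers share no spatial overlap."""


# ---------------------------------------------------------------------------
# Grid data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Georeferenced regular grid: shape, cell size and north-west corner.

    ``origin_x, origin_y`` locate the *outer* corner of cell (0, 0); rows
    increase southward.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_label: str = "local-metres"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise GridError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer bounding box."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (n_rows, n_cols) of x and y center coordinates."""
        cs = self.cell_size
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * cs
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * cs
        return np.meshgrid(xs, ys)

    def point_to_cell(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point; -1 where outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - y) / self.cell_size).astype(int)
        inside = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        row = np.where(inside, row, -1)
        col = np.where(inside, col, -1)
        return row, col

    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6


def _check_values(spec: GridSpec, values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != spec.shape:
        raise GridError(f"values shape {arr.shape} does not match grid {spec.shape}")
    return arr


@dataclass
class Raster:
    """Real-valued grid layer; NaN marks missing cells."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_values(self.spec, self.values)

    def copy(self) -> "Raster":
        return Raster(self.spec, self.values.copy())


@dataclass
class CategoricalRaster:
    """Integer-coded grid layer with a legend mapping code -> class name."""

    spec: GridSpec
    codes: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.codes = _check_values(self.spec, self.codes)
        present = np.unique(self.codes[np.isfinite(self.codes)]).astype(int)
        unknown = [int(c) for c in present if int(c) not in self.legend]
        if unknown:
            raise GridError(f"codes {unknown} missing from legend")


@dataclass
class BinaryMask:
    """Grid over {0, 1, missing(NaN)}."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_values(self.spec, self.values)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise GridError("BinaryMask values must be 0, 1 or missing")

    def count_ones(self) -> int:
        return int(np.nansum(self.values == 1))

    def one_set(self) -> np.ndarray:
        """Boolean array, True exactly where the mask is 1."""
        return self.values == 1


@dataclass
class PointSet:
    """Planar points (metres) with an optional attribute table."""

    coords: np.ndarray  # (n, 2)
    attrs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if self.coords.size and not np.isfinite(self.coords).all():
            raise GridError("point coordinates must be finite")
        if self.attrs is not None and len(self.attrs) != len(self.coords):
            raise GridError("attribute table length mismatch")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def x(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.coords[:, 1]


@dataclass
class PolygonSet:
    """Simple polygons with optional per-polygon attributes."""

    polygons: list[Polygon] = field(default_factory=list)
    attrs: pd.DataFrame | None = None

    @classmethod
    def from_vertices(
        cls, rings: Iterable[Sequence[tuple[float, float]]], attrs: pd.DataFrame | None = None
    ) -> "PolygonSet":
        return cls([Polygon(r) for r in rings], attrs)

    def __post_init__(self) -> None:
        for i, poly in enumerate(self.polygons):
            if len(poly.exterior.coords) < 4 or poly.area <= 0:
                raise GridError(f"polygon {i} is degenerate (needs >= 3 non-collinear vertices)")
        if self.attrs is not None and len(self.attrs) != len(self.polygons):
            raise GridError("attribute table length mismatch")

    def __len__(self) -> int:
        return len(self.polygons)


# ---------------------------------------------------------------------------
# Raster operations
# ---------------------------------------------------------------------------


def align_to(raster: Raster | CategoricalRaster, target: GridSpec):
    """Resample onto ``target`` by nearest neighbor (cell-center containment).

    Each target cell takes the value of the source cell containing its
    center; target centers outside the source extent become missing.
    """
    src = raster.spec
    if src == target:
        if isinstance(raster, CategoricalRaster):
            return CategoricalRaster(target, raster.codes.copy(), dict(raster.legend))
        return Raster(target, raster.values.copy())
    sx0, sy0, sx1, sy1 = src.extent
    tx0, ty0, tx1, ty1 = target.extent
    if sx0 >= tx1 or tx0 >= sx1 or sy0 >= ty1 or ty0 >= sy1:
        raise DisjointExtentError("source and target grids have no spatial overlap")
    cx, cy = target.cell_centers()
    row, col = src.point_to_cell(cx.ravel(), cy.ravel())
    out = np.full(cx.size, np.nan)
    inside = row >= 0
    src_vals = raster.codes if isinstance(raster, CategoricalRaster) else raster.values
    out[inside] = src_vals[row[inside], col[inside]]
    out = out.reshape(target.shape)
    if isinstance(raster, CategoricalRaster):
        return CategoricalRaster(target, out, dict(raster.legend))
    return Raster(target, out)


def threshold_mask(raster: Raster, max_value: float) -> BinaryMask:
    """1 where value <= max_value, 0 where it strictly exceeds; NaN propagates."""
    v = raster.values
    out = np.where(v <= max_value, 1.0, 0.0)
    out[~np.isfinite(v)] = np.nan
    return BinaryMask(raster.spec, out)


def class_mask(landcover: CategoricalRaster, excluded_classes: Iterable[str]) -> BinaryMask:
    """0 for excluded land-cover classes, 1 otherwise; NaN propagates."""
    excluded = set(excluded_classes)
    names = set(landcover.legend.values())
    unknown = excluded - names
    if unknown:
        raise GridError(f"excluded classes not in legend: {sorted(unknown)}")
    bad_codes = [code for code, name in landcover.legend.items() if name in excluded]
    codes = landcover.codes
    out = np.where(np.isin(codes, bad_codes), 0.0, 1.0)
    out[~np.isfinite(codes)] = np.nan
    return BinaryMask(landcover.spec, out)


def quantile_mask(raster: Raster, top_fraction: float) -> BinaryMask:
    """1 on cells in the top ``top_fraction`` of non-missing values.

    The cut is the (1 - top_fraction) linear-interpolation quantile; ties at
    the cut are all retained, so the retained fraction is >= top_fraction.
    """
    if not 0 < top_fraction <= 1:
        raise GridError("top_fraction must be in (0, 1]")
    v = raster.values
    finite = np.isfinite(v)
    if not finite.any():
        raise GridError("quantile_mask requires at least one non-missing cell")
    q = np.quantile(v[finite], 1.0 - top_fraction)
    out = np.where(v >= q, 1.0, 0.0)
    out[~finite] = np.nan
    return BinaryMask(raster.spec, out)


def distance_mask(points: PointSet, spec: GridSpec, radius_m: float) -> BinaryMask:
    """1 where a cell center lies within ``radius_m`` of any point."""
    if radius_m < 0:
        raise GridError("radius_m must be non-negative")
    if len(points) == 0:
        warnings.warn("distance_mask over an empty PointSet: all-zero mask", stacklevel=2)
        return BinaryMask(spec, np.zeros(spec.shape))
    cx, cy = spec.cell_centers()
    tree = cKDTree(points.coords)
    d, _ = tree.query(np.column_stack([cx.ravel(), cy.ravel()]), k=1)
    out = (d <= radius_m).astype(float).reshape(spec.shape)
    return BinaryMask(spec, out)


def polygon_mask(polys: PolygonSet, spec: GridSpec, invert: bool = False) -> BinaryMask:
    """1 where a cell center falls inside >= 1 polygon; ``invert`` swaps 0/1."""
    cx, cy = spec.cell_centers()
    inside = np.zeros(spec.shape, dtype=bool)
    if len(polys):
        union = shapely.unary_union(polys.polygons)
        shapely.prepare(union)
        inside = shapely.contains_xy(union, cx.ravel(), cy.ravel()).reshape(spec.shape)
    out = (~inside if invert else inside).astype(float)
    return BinaryMask(spec, out)


def sum_overlay(masks: Sequence[BinaryMask]) -> Raster:
    """Cellwise sum of binary layers; any missing layer makes the sum missing."""
    if not masks:
        raise GridError("sum_overlay requires at least one mask")
    spec = masks[0].spec
    for m in masks[1:]:
        if m.spec != spec:
            raise GridError("sum_overlay requires identical GridSpecs; align first")
    total = np.sum([m.values for m in masks], axis=0)
    return Raster(spec, total)


def equals_mask(sum_raster: Raster, k: int) -> BinaryMask:
    """1 where the summed layer equals k exactly; NaN propagates."""
    v = sum_raster.values
    out = np.where(v == k, 1.0, 0.0)
    out[~np.isfinite(v)] = np.nan
    return BinaryMask(sum_raster.spec, out)


def mask_intersect(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Cellwise logical AND; NaN propagates."""
    if a.spec != b.spec:
        raise GridError("mask_intersect requires identical GridSpecs")
    return BinaryMask(a.spec, a.values * b.values)


# ---------------------------------------------------------------------------
# I/O — ESRI ASCII grid, GeoJSON, CSV
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def write_ascii_grid(raster: Raster | CategoricalRaster | BinaryMask, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid (text; exact float round-trip)."""
    spec = raster.spec
    vals = raster.codes if isinstance(raster, CategoricalRaster) else raster.values
    out = np.where(np.isfinite(vals), vals, _NODATA)
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x!r}\n"
        f"yllcorner {spec.origin_y - spec.n_rows * spec.cell_size!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {_NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.17g")


def read_ascii_grid(path: str | Path, crs_label: str = "local-metres") -> Raster:
    with open(path) as fh:
        head = {}
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        vals = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(head["nrows"]), int(head["ncols"])
    spec = GridSpec(
        n_rows,
        n_cols,
        head["cellsize"],
        origin_x=head["xllcorner"],
        origin_y=head["yllcorner"] + n_rows * head["cellsize"],
        crs_label=crs_label,
    )
    vals[vals == head["nodata_value"]] = np.nan
    return Raster(spec, vals)


def read_ascii_mask(path: str | Path) -> BinaryMask:
    r = read_ascii_grid(path)
    return BinaryMask(r.spec, r.values)


def write_points_geojson(points: PointSet, path: str | Path) -> None:
    feats = []
    for i, (x, y) in enumerate(points.coords):
        props = {} if points.attrs is None else _json_safe(points.attrs.iloc[i].to_dict())
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": props,
            }
        )
    _dump_geojson(feats, path)


def write_polygons_geojson(polys: PolygonSet, path: str | Path) -> None:
    feats = []
    for i, poly in enumerate(polys.polygons):
        props = {} if polys.attrs is None else _json_safe(polys.attrs.iloc[i].to_dict())
        feats.append({"type": "Feature", "geometry": mapping(poly), "properties": props})
    _dump_geojson(feats, path)


def read_points_geojson(path: str | Path) -> PointSet:
    feats = json.loads(Path(path).read_text())["features"]
    coords = np.array([f["geometry"]["coordinates"] for f in feats], dtype=float).reshape(-1, 2)
    attrs = pd.DataFrame([f.get("properties") or {} for f in feats]) if feats else None
    if attrs is not None and attrs.empty:
        attrs = None
    return PointSet(coords, attrs)


def read_polygons_geojson(path: str | Path) -> PolygonSet:
    feats = json.loads(Path(path).read_text())["features"]
    polys = [shape(f["geometry"]) for f in feats]
    attrs = pd.DataFrame([f.get("properties") or {} for f in feats]) if feats else None
    if attrs is not None and attrs.empty:
        attrs = None
    return PolygonSet(polys, attrs)


def read_points_csv(path: str | Path, x_col: str = "x", y_col: str = "y") -> PointSet:
    df = pd.read_csv(path, float_precision="round_trip")
    coords = df[[x_col, y_col]].to_numpy(dtype=float)
    attrs = df.drop(columns=[x_col, y_col])
    return PointSet(coords, attrs if len(attrs.columns) else None)


def write_points_csv(points: PointSet, path: str | Path) -> None:
    df = pd.DataFrame(points.coords, columns=["x", "y"])
    if points.attrs is not None:
        df = pd.concat([df, points.attrs.reset_index(drop=True)], axis=1)
    df.to_csv(path, index=False)


def _json_safe(d: Mapping) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        out[str(k)] = v
    return out


def _dump_geojson(features: list, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
    )
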