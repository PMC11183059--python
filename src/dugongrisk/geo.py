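"""Planar raster/vector data model and I/O.

Single-band rasters carry a value matrix, an affine georeference, and a
boolean validity mask (``False`` = nodata/land).  Coordinates are planar
(kilometres in the synthetic scenarios), row 0 is the northernmost row, and
cell values refer to cell centers.  Point-to-cell membership uses half-open
intervals ``[x0, x0+w) x (y0-h, y0]`` so boundary assignment is
deterministic.  Equal-area cells are assumed throughout; a ``crs_tag`` is
carried opaquely and no reprojection is performed.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Polygon, mapping, shape

__all__ = [
    "DomainError",
    "GridFormatError",
    "GridTransform",
    "Grid",
    "PolygonSet",
    "PointSet",
    "read_grid",
    "write_grid",
    "align_to_template",
    "minmax_normalize",
    "rasterize",
    "masked_area",
    "read_polygons",
    "write_polygons",
]

NODATA = -9999.0

# GeoTIFF tag ids used for the georeference.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class DomainError(ValueError):
    """An operation's domain precondition was violated."""


class GridFormatError(ValueError):
    """A raster file did not parse as the named format."""


@dataclass(frozen=True)
class GridTransform:
    """Affine georeference: top-left corner origin plus cell size.

    ``x0, y0`` locate the outer corner of cell (0, 0); ``cell_w`` and
    ``cell_h`` are positive cell dimensions, rows advancing southward.
    """

    x0: float
    y0: float
    cell_w: float
    cell_h: float

    def __post_init__(self) -> None:
        if self.cell_w == 0 or self.cell_h == 0:
            raise ValueError("cell dimensions must be nonzero")

    def cell_center(self, row, col):
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell_w
        y = self.y0 - (np.asarray(row) + 0.5) * self.cell_h
        return x, y

    def point_to_cell(self, x, y):
        """Map coordinates to (row, col) under the half-open convention."""
        col = np.floor((np.asarray(x, dtype=float) - self.x0) / self.cell_w)
        row = np.floor((self.y0 - np.asarray(y, dtype=float)) / self.cell_h)
        return row.astype(int), col.astype(int)

    def bounds(self, shape: tuple[int, int]) -> tuple[float, float, float, float]:
        rows, cols = shape
        return (
            self.x0,
            self.y0 - rows * self.cell_h,
            self.x0 + cols * self.cell_w,
            self.y0,
        )


@dataclass
class Grid:
    """Single-band raster with validity mask and cell area."""

    values: np.ndarray
    transform: GridTransform
    mask: np.ndarray
    crs_tag: str = "planar-km"
    cell_area_km2: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.cell_area_km2 is None:
            self.cell_area_km2 = abs(self.transform.cell_w * self.transform.cell_h)
        if self.cell_area_km2 <= 0:
            raise ValueError("cell_area_km2 must be positive")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("valid cells must hold finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def with_values(self, values, mask=None, degenerate: bool = False) -> "Grid":
        return Grid(
            values=np.asarray(values, dtype=float),
            transform=self.transform,
            mask=self.mask.copy() if mask is None else np.asarray(mask, dtype=bool),
            crs_tag=self.crs_tag,
            cell_area_km2=self.cell_area_km2,
            degenerate=degenerate,
        )

    def cell_centers(self):
        rows, cols = self.shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return self.transform.cell_center(rr, cc)

    def same_template(self, other: "Grid", atol: float = 1e-9) -> bool:
        t, u = self.transform, other.transform
        return self.shape == other.shape and np.allclose(
            [t.x0, t.y0, t.cell_w, t.cell_h], [u.x0, u.y0, u.cell_w, u.cell_h], atol=atol
        )


@dataclass
class PolygonSet:
    """Labelled closed polygons sharing a crs tag."""

    polygons: list[Polygon]
    labels: list[str] = field(default_factory=list)
    crs_tag: str = "planar-km"

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [f"poly_{i}" for i in range(len(self.polygons))]
        if len(self.labels) != len(self.polygons):
            raise ValueError("labels/polygons length mismatch")
        for poly in self.polygons:
            coords = list(poly.exterior.coords)
            if len(set(coords[:-1])) < 3:
                raise ValueError("polygon rings need >= 3 distinct vertices")

    def __len__(self) -> int:
        return len(self.polygons)


@dataclass
class PointSet:
    """Occurrence/survey records with coordinates and optional metadata.

    Backed by a DataFrame with columns x, y, date, season, count, source.
    """

    df: pd.DataFrame

    COLUMNS = ("x", "y", "date", "season", "count", "source")

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col in ("x", "y", "count") else None
        df = df[list(self.COLUMNS)].reset_index(drop=True)
        if len(df) and not np.all(np.isfinite(df[["x", "y"]].to_numpy(dtype=float))):
            raise ValueError("point coordinates must be finite")
        counts = df["count"].dropna()
        if len(counts) and (counts.astype(float) < 0).any():
            raise ValueError("counts must be nonnegative")
        self.df = df

    @classmethod
    def from_arrays(cls, x, y, date=None, season=None, count=None, source="synthetic"):
        n = len(np.atleast_1d(x))
        return cls(
            pd.DataFrame(
                {
                    "x": np.asarray(x, dtype=float),
                    "y": np.asarray(y, dtype=float),
                    "date": date if date is not None else [None] * n,
                    "season": season if season is not None else [None] * n,
                    "count": count if count is not None else [None] * n,
                    "source": source if not np.isscalar(source) else [source] * n,
                }
            )
        )

    @classmethod
    def read_csv(cls, path) -> "PointSet":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def x(self) -> np.ndarray:
        return self.df["x"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy(dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return self.df["count"].to_numpy(dtype=float)

    def subset(self, index) -> "PointSet":
        return PointSet(self.df.iloc[np.asarray(index)].reset_index(drop=True))

    def cells(self, grid: Grid):
        """Map points to (row, col) on ``grid``; no validity filtering."""
        return grid.transform.point_to_cell(self.x, self.y)


# ---------------------------------------------------------------------------
# Raster I/O


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    if suffix in (".asc", ".txt"):
        return "ascii"
    raise GridFormatError(f"cannot infer raster format from {path.name!r}")


def read_grid(path, format: str | None = None) -> Grid:
    """Read a single-band raster (GeoTIFF or ESRI ASCII grid)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt == "ascii":
        return _read_ascii(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    raise GridFormatError(f"unknown raster format {fmt!r}")


def write_grid(grid: Grid, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "ascii":
        _write_ascii(grid, path)
    elif fmt == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise GridFormatError(f"unknown raster format {fmt!r}")


def _read_ascii(path: Path) -> Grid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required.issubset(header):
        raise GridFormatError(f"missing ASCII grid header keys in {path.name}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.array([v for row in rows for v in row], dtype=float)
    if values.size != nrows * ncols:
        raise GridFormatError(
            f"{path.name}: expected {nrows * ncols} values, found {values.size}"
        )
    values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value", NODATA)
    mask = values != nodata
    cell = header["cellsize"]
    transform = GridTransform(
        x0=header["xllcorner"], y0=header["yllcorner"] + nrows * cell, cell_w=cell, cell_h=cell
    )
    values = np.where(mask, values, 0.0)
    return Grid(values=values, transform=transform, mask=mask)


def _write_ascii(grid: Grid, path: Path) -> None:
    t = grid.transform
    if not np.isclose(t.cell_w, t.cell_h):
        raise GridFormatError("ESRI ASCII grids require square cells")
    rows, cols = grid.shape
    out = np.where(grid.mask, grid.values, NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write(f"xllcorner {float(t.x0)!r}\n")
        fh.write(f"yllcorner {float(t.y0 - rows * t.cell_h)!r}\n")
        fh.write(f"cellsize {float(t.cell_w)!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        for r in range(rows):
            fh.write(" ".join(repr(float(v)) for v in out[r]) + "\n")


def _read_geotiff(path: Path) -> Grid:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = np.asarray(page.asarray(), dtype=float)
        if values.ndim != 2:
            raise GridFormatError("multi-band imagery is not supported")
        tags = page.tags
        try:
            scale = tags[_TAG_PIXEL_SCALE].value
            tie = tags[_TAG_TIEPOINT].value
        except KeyError as exc:
            raise GridFormatError(f"{path.name}: missing GeoTIFF georeference tags") from exc
        nodata = NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
        crs_tag = "planar-km"
        if "ImageDescription" in tags and tags["ImageDescription"].value:
            crs_tag = str(tags["ImageDescription"].value)
    cell_w, cell_h = float(scale[0]), float(scale[1])
    # Tiepoint maps raster (i, j) = (0, 0) to the top-left model corner.
    x0 = float(tie[3]) - float(tie[0]) * cell_w
    y0 = float(tie[4]) + float(tie[1]) * cell_h
    mask = ~np.isclose(values, nodata) & np.isfinite(values)
    values = np.where(mask, values, 0.0)
    transform = GridTransform(x0=x0, y0=y0, cell_w=cell_w, cell_h=cell_h)
    return Grid(values=values, transform=transform, mask=mask, crs_tag=crs_tag)


def _write_geotiff(grid: Grid, path: Path) -> None:
    import tifffile

    t = grid.transform
    out = np.where(grid.mask, grid.values, NODATA).astype(np.float64)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (t.cell_w, t.cell_h, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(NODATA)),
    ]
    tifffile.imwrite(
        str(path), out, extratags=extratags, description=grid.crs_tag, photometric="minisblack"
    )


# ---------------------------------------------------------------------------
# Grid operations


def align_to_template(grid: Grid, template: Grid, method: str = "bilinear") -> Grid:
    """Resample ``grid`` onto ``template``'s shape and transform.

    ``nearest`` preserves the input's value set; ``bilinear`` output is
    bounded by the input's valid min/max.  Output mask is the intersection of
    the template mask with cells resolvable from valid input.
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown resampling method {method!r}")
    gb, tb = grid.transform.bounds(grid.shape), template.transform.bounds(template.shape)
    if gb[2] <= tb[0] or tb[2] <= gb[0] or gb[3] <= tb[1] or tb[3] <= gb[1]:
        raise DomainError("grid and template extents are disjoint")

    xs, ys = template.cell_centers()
    gt = grid.transform
    col_f = (xs - gt.x0) / gt.cell_w - 0.5
    row_f = (gt.y0 - ys) / gt.cell_h - 0.5
    rows, cols = grid.shape
    inside = (col_f >= -0.5) & (col_f <= cols - 0.5) & (row_f >= -0.5) & (row_f <= rows - 0.5)

    if method == "nearest":
        rr = np.clip(np.round(row_f).astype(int), 0, rows - 1)
        cc = np.clip(np.round(col_f).astype(int), 0, cols - 1)
        values = grid.values[rr, cc]
        valid = grid.mask[rr, cc] & inside
    else:
        fill = float(np.mean(grid.valid_values())) if grid.mask.any() else 0.0
        filled = np.where(grid.mask, grid.values, fill)
        values = ndimage.map_coordinates(filled, [row_f, col_f], order=1, mode="nearest")
        mask_frac = ndimage.map_coordinates(
            grid.mask.astype(float), [row_f, col_f], order=1, mode="nearest"
        )
        valid = (mask_frac > 1.0 - 1e-9) & inside
    mask = valid & template.mask
    return Grid(
        values=np.where(mask, values, 0.0),
        transform=template.transform,
        mask=mask,
        crs_tag=grid.crs_tag,
        cell_area_km2=template.cell_area_km2,
    )


def minmax_normalize(grid: Grid) -> Grid:
    """Affinely rescale valid values to [0, 1], preserving order.

    A constant input yields all zeros with the ``degenerate`` flag set.
    """
    if not grid.mask.any():
        raise DomainError("cannot normalize a grid with no valid cells")
    vals = grid.valid_values()
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        warnings.warn("minmax_normalize: constant grid, returning zeros", stacklevel=2)
        return grid.with_values(np.zeros_like(grid.values), degenerate=True)
    out = np.where(grid.mask, (grid.values - lo) / (hi - lo), 0.0)
    return grid.with_values(out)


def rasterize(polys: PolygonSet, template: Grid) -> Grid:
    """Burn polygons to a 0/1 membership grid by the cell-center rule."""
    if polys.crs_tag != template.crs_tag:
        raise DomainError(
            f"crs mismatch: polygons {polys.crs_tag!r} vs template {template.crs_tag!r}"
        )
    xs, ys = template.cell_centers()
    out = np.zeros(template.shape, dtype=float)
    flat_x, flat_y = xs.ravel(), ys.ravel()
    hit = np.zeros(flat_x.shape, dtype=bool)
    for poly in polys.polygons:
        hit |= shapely.contains_xy(poly, flat_x, flat_y)
    out.ravel()[hit] = 1.0
    return template.with_values(out)


def masked_area(mask_grid: Grid, cell_area_km2: float | None = None) -> float:
    """Total area (km²) of the 1-cells of a binary grid."""
    area = cell_area_km2 if cell_area_km2 is not None else mask_grid.cell_area_km2
    vals = mask_grid.valid_values()
    if vals.size and not np.all(np.isin(vals, (0.0, 1.0))):
        raise DomainError("masked_area expects a 0/1 grid")
    return float(vals.sum()) * float(area)


# ---------------------------------------------------------------------------
# Vector I/O


def read_polygons(path) -> PolygonSet:
    """Read polygons from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        doc = json.load(fh)
    polygons, labels = [], []
    crs_tag = doc.get("crs_tag", "planar-km")
    for i, feat in enumerate(doc.get("features", [])):
        geom = shape(feat["geometry"])
        geoms = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
        for g in geoms:
            polygons.append(Polygon(g.exterior.coords))
            labels.append(str(feat.get("properties", {}).get("label", f"poly_{i}")))
    return PolygonSet(polygons=polygons, labels=labels, crs_tag=crs_tag)


def write_polygons(polys: PolygonSet, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"label": label},
            "geometry": mapping(poly),
        }
        for poly, label in zip(polys.polygons, polys.labels)
    ]
    doc = {"type": "FeatureCollection", "crs_tag": polys.crs_tag, "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)
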