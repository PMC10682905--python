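"""Raster data model and I/O.

Grids are top-left-origin, row-major, with y decreasing as the row index
increases. A cell's location is its center for every point-in-cell and
cell-in-polygon test. Two geometries are co-registered iff all numeric
fields agree within ``GEOM_TOL`` degrees.

Supported on-disk dialects: single-band GeoTIFF (float32 + nodata tag)
and ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint

from nichekit.errors import FormatError, GeometryError, InputError, UnsupportedInputError

GEOM_TOL = 1e-9

# GeoTIFF tag ids used for georeferencing (GeoTIFF spec / GDAL convention)
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridGeometry:
    """Regular lon/lat grid geometry.

    ``x_origin``/``y_origin`` give the outer corner of the top-left cell
    (west edge, north edge). Cells are square, ``cell_size`` degrees.
    """

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    cell_size: float
    crs_tag: str = "geographic lon/lat"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise InputError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise InputError("cell_size must be > 0")

    def co_registered(self, other: "GridGeometry") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.x_origin - other.x_origin) <= GEOM_TOL
            and abs(self.y_origin - other.y_origin) <= GEOM_TOL
            and abs(self.cell_size - other.cell_size) <= GEOM_TOL
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lon, lat) arrays of shape (n_rows, n_cols) of cell centers."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.x_origin + (cols + 0.5) * self.cell_size
        y = self.y_origin - (rows + 0.5) * self.cell_size
        lon, lat = np.meshgrid(x, y)
        return lon, lat

    def locate(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col) with the half-open cell rule.

        A point belongs to the cell with x in [left, right) and
        y in (top, bottom] (y decreasing downward: lat in [bottom, top)
        except the grid's own top edge which is excluded).  Returns
        (row, col, inside) where ``inside`` flags points on the grid.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x_origin) / self.cell_size).astype(np.int64)
        # y rule: row r covers y_origin - r*cs >= lat > y_origin - (r+1)*cs
        # i.e. d = y_origin - lat in (r*cs, (r+1)*cs] -> r = ceil(d/cs) - 1
        d = (self.y_origin - lat) / self.cell_size
        row = np.ceil(d).astype(np.int64) - 1
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return row, col, inside


@dataclass
class Layer:
    """A named single-band raster. Masked cells carry no information."""

    name: str
    geometry: GridGeometry
    values: np.ndarray
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.shape:
            raise InputError(
                f"layer {self.name!r}: values shape {self.values.shape} != geometry {self.geometry.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise InputError(f"layer {self.name!r}: mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise InputError(f"layer {self.name!r}: non-finite values on unmasked cells")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def copy(self, name: str | None = None) -> "Layer":
        return Layer(
            name=name if name is not None else self.name,
            geometry=self.geometry,
            values=self.values.copy(),
            nodata_mask=self.nodata_mask.copy(),
        )


class EnvStack:
    """Ordered collection of co-registered, uniquely named layers."""

    def __init__(self, layers: Sequence[Layer]):
        layers = list(layers)
        if not layers:
            raise InputError("EnvStack needs at least one layer")
        names = [ly.name for ly in layers]
        if len(set(names)) != len(names):
            raise InputError("layer names must be unique")
        geom = layers[0].geometry
        for ly in layers[1:]:
            if not geom.co_registered(ly.geometry):
                raise GeometryError(f"layer {ly.name!r} is not co-registered with {layers[0].name!r}")
        self.layers: list[Layer] = layers
        self.geometry = geom

    @property
    def names(self) -> list[str]:
        return [ly.name for ly in self.layers]

    @property
    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.geometry.shape, dtype=bool)
        for ly in self.layers:
            mask &= ly.valid_mask
        return mask

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> Layer:
        for ly in self.layers:
            if ly.name == name:
                return ly
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def values_table(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Stack per-layer values at (rows, cols) into an (n, n_layers) table."""
        return np.column_stack([ly.values[rows, cols] for ly in self.layers])

    def valid_cell_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (rows, cols, table) over the stack-wide valid mask."""
        rows, cols = np.nonzero(self.valid_mask)
        return rows, cols, self.values_table(rows, cols)

    def with_mask(self, extra_mask: np.ndarray) -> "EnvStack":
        """New stack with cells where ``extra_mask`` is False masked out everywhere."""
        out = []
        for ly in self.layers:
            new = ly.copy()
            new.nodata_mask = new.nodata_mask | ~extra_mask
            out.append(new)
        return EnvStack(out)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def _read_ascii(path: Path, name: str) -> Layer:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path, "r") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _ASCII_HEADER_KEYS:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for k in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if k not in header:
            raise FormatError(f"{path}: ESRI ASCII header missing {k!r}")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    try:
        values = np.loadtxt(data_lines, dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: could not parse grid body: {exc}") from exc
    values = values.reshape(n_rows, n_cols)
    cs = header["cellsize"]
    geom = GridGeometry(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * cs,
        cell_size=cs,
    )
    mask = values == nodata
    values = np.where(mask, 0.0, values)
    return Layer(name=name, geometry=geom, values=values, nodata_mask=mask)


def _write_ascii(layer: Layer, path: Path) -> None:
    g = layer.geometry
    vals = np.where(layer.nodata_mask, DEFAULT_NODATA, layer.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.x_origin!r}\n")
        fh.write(f"yllcorner {g.y_origin - g.n_rows * g.cell_size!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {DEFAULT_NODATA!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def _read_geotiff(path: Path, name: str) -> Layer:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tf:
            if len(tf.pages) > 1:
                raise UnsupportedInputError(f"{path}: multi-page TIFF not supported")
            page = tf.pages[0]
            if page.samplesperpixel != 1:
                raise UnsupportedInputError(f"{path}: multi-band TIFF not supported")
            values = page.asarray().astype(np.float64)
            tags = page.tags
            if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
                raise FormatError(f"{path}: missing GeoTIFF georeferencing tags")
            scale = tags[_TAG_PIXEL_SCALE].value
            tie = tags[_TAG_TIEPOINT].value
            nodata = None
            if _TAG_GDAL_NODATA in tags:
                nodata = float(tags[_TAG_GDAL_NODATA].value)
    except (UnsupportedInputError, FormatError):
        raise
    except Exception as exc:
        raise FormatError(f"{path}: not a readable TIFF: {exc}") from exc
    if values.ndim != 2:
        raise UnsupportedInputError(f"{path}: expected a 2-D single-band raster")
    sx, sy = float(scale[0]), float(scale[1])
    if abs(sx - sy) > GEOM_TOL:
        raise UnsupportedInputError(f"{path}: non-square cells ({sx} x {sy})")
    # tiepoint maps raster (i,j,k) -> model (x,y,z); we write (0,0,0)->origin
    x_origin = float(tie[3]) - float(tie[0]) * sx
    y_origin = float(tie[4]) + float(tie[1]) * sy
    geom = GridGeometry(
        n_rows=values.shape[0], n_cols=values.shape[1],
        x_origin=x_origin, y_origin=y_origin, cell_size=sx,
    )
    if nodata is None:
        mask = ~np.isfinite(values)
    else:
        mask = (values == nodata) | ~np.isfinite(values)
    values = np.where(mask, 0.0, values)
    return Layer(name=name, geometry=geom, values=values, nodata_mask=mask)


def _write_geotiff(layer: Layer, path: Path) -> None:
    import tifffile

    g = layer.geometry
    vals = np.where(layer.nodata_mask, DEFAULT_NODATA, layer.values).astype(np.float32)
    nodata_str = repr(DEFAULT_NODATA) + "\x00"
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.x_origin, g.y_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", len(nodata_str), nodata_str),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_raster(path: str | Path, name: str | None = None) -> Layer:
    """Read a single-band raster (GeoTIFF or ESRI ASCII grid) into a Layer.

    The dialect is sniffed from the file's magic bytes; ``name`` defaults
    to the file stem.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    try:
        with open(path, "rb") as fh:
            magic = fh.read(4)
    except OSError as exc:
        raise FormatError(f"{path}: unreadable: {exc}") from exc
    if magic[:2] in (b"II", b"MM"):
        return _read_geotiff(path, name)
    return _read_ascii(path, name)


def write_raster(layer: Layer, path: str | Path, dialect: str = "ascii") -> None:
    """Write a Layer; ``dialect`` is 'ascii' or 'geotiff'."""
    path = Path(path)
    if dialect == "ascii":
        _write_ascii(layer, path)
    elif dialect == "geotiff":
        _write_geotiff(layer, path)
    else:
        raise InputError(f"unknown raster dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Cropping
# ---------------------------------------------------------------------------

def buffered_hull(points: Iterable[tuple[float, float]], buffer_deg: float):
    """Convex hull of lon/lat points, buffered outward by ``buffer_deg``."""
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise GeometryError("need >= 3 points for a convex hull")
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon":
        raise GeometryError("points are collinear; convex hull is degenerate")
    if buffer_deg > 0:
        hull = hull.buffer(buffer_deg)
    return hull


def crop_to_hull(
    stack: EnvStack,
    points: Iterable[tuple[float, float]],
    buffer_deg: float = 3.0,
) -> EnvStack:
    """Mask cells whose centers fall outside the buffered convex hull.

    Mask-only crop: the grid geometry is unchanged. The default 3-degree
    buffer matches the pipeline's model-area convention.
    """
    hull = buffered_hull(points, buffer_deg)
    lon, lat = stack.geometry.cell_centers()
    inside = shapely.intersects_xy(hull, lon.ravel(), lat.ravel()).reshape(lon.shape)
    return stack.with_mask(inside)


def pixel_area(mask: np.ndarray, geometry: GridGeometry | None = None, cos_weighted: bool = False) -> float:
    """Area of a boolean mask as a pixel count (canonical), or cos(lat)-weighted."""
    if not cos_weighted:
        return float(np.count_nonzero(mask))
    if geometry is None:
        raise InputError("cos-weighted area needs the grid geometry")
    _, lat = geometry.cell_centers()
    return float(np.sum(np.cos(np.radians(lat))[mask]))
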