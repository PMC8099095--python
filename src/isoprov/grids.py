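"""Equal-area raster grids, covariate stacks and point extraction.

All spatial analysis runs on a single equal-area projected grid with square
cells, so cell counting is area arithmetic. Grids are stored row-major with
the origin at the upper-left corner; cells are half-open,
``[x, x + cell) x (y - cell, y]``, so a point on a shared edge belongs to the
cell to its right / below. Rasters are serialized as single-band ESRI ASCII
(.asc) text files.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Callable, Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage


class ProjectionError(ValueError):
    """Raised when coordinates cannot be brought into a grid's frame."""


# ---------------------------------------------------------------------------
# coordinate transforms
#
# A transform maps (lon, lat) in decimal degrees WGS84 into the projected
# (x, y) metres of a grid. Only simple analytic frames are supported:
#   "local"           -- coordinates are already projected metres (identity)
#   "equirect:<lat0>" -- equirectangular about reference latitude lat0,
#                        x = R*cos(lat0)*lon_rad, y = R*lat_rad (approximately
#                        equal-area near lat0; adequate for regional grids)
# ---------------------------------------------------------------------------

_EARTH_RADIUS_M = 6_371_000.0


def projector(crs: str) -> Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Return a (lon, lat) -> (x, y) callable for a supported CRS string."""
    if crs == "local":
        return lambda lon, lat: (np.asarray(lon, float), np.asarray(lat, float))
    if crs.startswith("equirect:"):
        try:
            lat0 = float(crs.split(":", 1)[1])
        except ValueError as exc:
            raise ProjectionError(f"bad reference latitude in CRS {crs!r}") from exc
        k = _EARTH_RADIUS_M * np.cos(np.deg2rad(lat0))

        def _proj(lon, lat):
            lon = np.asarray(lon, float)
            lat = np.asarray(lat, float)
            return k * np.deg2rad(lon), _EARTH_RADIUS_M * np.deg2rad(lat)

        return _proj
    raise ProjectionError(f"unsupported CRS {crs!r}")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an equal-area analysis grid with square cells.

    Parameters
    ----------
    crs : str
        Projection identifier (see :func:`projector`). Assumed equal-area
        for all area arithmetic.
    cell_size : float
        Cell edge in metres.
    xmin, ymax : float
        Projected coordinates of the grid's upper-left corner.
    nrows, ncols : int
        Grid dimensions.
    """

    crs: str = "local"
    cell_size: float = 1000.0
    xmin: float = 0.0
    ymax: float = 0.0
    nrows: int = 1
    ncols: int = 1

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.cell_size

    @property
    def ymin(self) -> float:
        return self.ymax - self.nrows * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Projected (x, y) coordinates of every cell center (2-D arrays)."""
        xs = self.xmin + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.ymax - (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map projected points to (row, col) under the half-open convention.

        Returns ``(rows, cols, inside)``; indices are clipped for points
        outside the extent, flagged by ``inside == False``.
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        col = np.floor((x - self.xmin) / self.cell_size).astype(int)
        # cells are (y - cell, y] in y: a point on a horizontal shared edge
        # belongs to the cell below it, which floor on the flipped axis gives
        row = np.floor((self.ymax - y) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        return (np.clip(row, 0, self.nrows - 1), np.clip(col, 0, self.ncols - 1), inside)


@dataclass
class RasterGrid:
    """One named single-band grid: values plus a nodata mask on a GridSpec."""

    spec: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, bool)
        if self.nodata_mask.shape != self.spec.shape:
            raise ValueError("nodata_mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError(f"non-finite values outside nodata mask in {self.name!r}")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def copy_with(self, values: np.ndarray, name: str | None = None) -> "RasterGrid":
        return RasterGrid(self.spec, values, self.nodata_mask.copy(),
                          self.name if name is None else name)


@dataclass
class CovariateStack:
    """Aligned covariate grids sharing one GridSpec."""

    spec: GridSpec
    layers: dict[str, RasterGrid] = field(default_factory=dict)

    def add(self, grid: RasterGrid) -> None:
        if grid.spec != self.spec:
            raise ValueError(f"layer {grid.name!r} is not on the stack grid")
        if not grid.name:
            raise ValueError("layer must be named")
        self.layers[grid.name] = grid

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def combined_valid_mask(self, names: Iterable[str] | None = None) -> np.ndarray:
        mask = np.ones(self.spec.shape, bool)
        for n in (self.names if names is None else names):
            mask &= self.layers[n].valid_mask
        return mask

    def as_matrix(self, names: Iterable[str] | None = None) -> pd.DataFrame:
        """Flatten selected layers to an (n_cells, n_layers) DataFrame."""
        names = self.names if names is None else list(names)
        return pd.DataFrame({n: self.layers[n].values.ravel() for n in names})


@dataclass
class Isoscape:
    """Mean + SD grid pair for one isotopic system.

    ``sd`` may be a full grid (spatially explicit uncertainty, e.g. a
    published Sr isoscape) or a scalar applied everywhere (the constant-RMSE
    convention used for the sulfur surface).
    """

    system: str  # "S", "O_precip", "Sr", ...
    mean: RasterGrid
    sd: RasterGrid | float
    note: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.sd, RasterGrid):
            if self.sd.spec != self.mean.spec:
                raise ValueError("mean and sd grids must share a GridSpec")
            bad = self.mean.valid_mask & (self.sd.values <= 0)
            if bad.any():
                raise ValueError("sd must be positive wherever mean is valid")
        elif self.sd <= 0:
            raise ValueError("scalar sd must be positive")

    @property
    def spec(self) -> GridSpec:
        return self.mean.spec

    def sd_values(self) -> np.ndarray:
        if isinstance(self.sd, RasterGrid):
            return self.sd.values
        return np.full(self.mean.spec.shape, float(self.sd))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def resample_to_grid(source: RasterGrid, target: GridSpec,
                     method: str = "bilinear") -> RasterGrid:
    """Resample/reproject a grid onto a target GridSpec.

    ``method`` is ``nearest`` or ``mode`` for discrete layers and
    ``bilinear`` for continuous ones. Source and target frames must be
    related by the supported analytic transforms; nodata propagates (a
    bilinear output cell is nodata if any contributing source cell is).
    """
    if method not in {"nearest", "bilinear", "mode"}:
        raise ValueError(f"unknown resampling method {method!r}")
    src = source.spec
    if src == target:
        return RasterGrid(target, source.values.copy(), source.nodata_mask.copy(),
                          source.name)
    if src.crs != target.crs:
        # only identical frames or degree->metre equirect pairs are supported
        raise ProjectionError(
            f"cannot reproject from CRS {src.crs!r} to {target.crs!r}")

    tx, ty = target.cell_centers()
    # fractional source pixel coordinates of the target cell centers
    # (pixel-center convention: source cell (r, c) center sits at index (r, c))
    fc = (tx - src.xmin) / src.cell_size - 0.5
    fr = (src.ymax - ty) / src.cell_size - 0.5

    vals = np.where(source.nodata_mask, np.nan, source.values)
    if method == "bilinear":
        out = ndimage.map_coordinates(vals, [fr, fc], order=1, mode="nearest",
                                      cval=np.nan)
    elif method == "nearest":
        out = ndimage.map_coordinates(vals, [fr, fc], order=0, mode="nearest")
    else:  # mode: majority vote of source cells falling in each target cell
        out = _mode_resample(source, target)
    outside = ((tx < src.xmin) | (tx > src.xmax) |
               (ty < src.ymin) | (ty > src.ymax))
    out = np.where(outside, np.nan, out)
    return RasterGrid(target, out, ~np.isfinite(out), source.name)


def _mode_resample(source: RasterGrid, target: GridSpec) -> np.ndarray:
    sx, sy = source.spec.cell_centers()
    rows, cols, inside = target.index_of(sx.ravel(), sy.ravel())
    vals = np.where(source.nodata_mask, np.nan, source.values).ravel()
    ok = inside & np.isfinite(vals)
    out = np.full(target.shape, np.nan)
    if ok.any():
        flat = rows[ok] * target.ncols + cols[ok]
        df = pd.DataFrame({"cell": flat, "v": vals[ok]})
        # deterministic tie-break: smallest value wins
        modes = df.groupby("cell")["v"].agg(lambda s: s.mode().min())
        out.ravel()[modes.index.to_numpy()] = modes.to_numpy()
    empty = ~np.isfinite(out)
    if empty.any():
        # fall back to nearest for target cells that captured no source center
        near = resample_to_grid(source, target, method="nearest")
        out = np.where(empty, near.values, out)
    return out


def extract_at_points(stack: CovariateStack,
                      points: Iterable[tuple[str, float, float]]) -> pd.DataFrame:
    """Extract stack layer values at (site_id, lat, lon) points.

    Each site receives the value of the cell containing its projected
    coordinate. Sites on nodata cells or outside the extent get NaN for the
    affected layers and a logged warning; extraction never fails on geometry.

    Returns a DataFrame indexed by site_id with columns ``x``, ``y`` and one
    column per layer.
    """
    pts = list(points)
    ids = [p[0] for p in pts]
    lats = np.array([p[1] for p in pts], float)
    lons = np.array([p[2] for p in pts], float)
    proj = projector(stack.spec.crs)
    x, y = proj(lons, lats)
    rows, cols, inside = stack.spec.index_of(x, y)
    if not inside.all():
        n_out = int((~inside).sum())
        warnings.warn(f"{n_out} point(s) fall outside the grid extent; "
                      "their covariate values are marked invalid")
    out = pd.DataFrame({"x": x, "y": y}, index=pd.Index(ids, name="site_id"))
    for name, layer in stack.layers.items():
        v = layer.values[rows, cols].astype(float)
        v[~inside | layer.nodata_mask[rows, cols]] = np.nan
        out[name] = v
    return out


def distance_to_coast(land_mask: RasterGrid | np.ndarray,
                      spec: GridSpec | None = None) -> RasterGrid:
    """Euclidean distance (km) from every land cell to the nearest sea cell.

    Distances are measured between cell centers; sea cells are exactly 0.
    """
    if isinstance(land_mask, RasterGrid):
        spec = land_mask.spec
        land = land_mask.values.astype(bool)
    else:
        if spec is None:
            raise ValueError("spec required when land_mask is a bare array")
        land = np.asarray(land_mask, bool)
    if land.all():
        raise ValueError("mask is all land: no coast to measure from")
    if not land.any():
        raise ValueError("mask is all sea: nothing to measure")
    d = ndimage.distance_transform_edt(land, sampling=spec.cell_size)
    return RasterGrid(spec, d / 1000.0, np.zeros(spec.shape, bool), "r.distance")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (text; single band, square cells)
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def write_ascii_grid(grid: RasterGrid, path) -> None:
    vals = np.where(grid.nodata_mask, _NODATA, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.spec.ncols}\n")
        fh.write(f"nrows {grid.spec.nrows}\n")
        fh.write(f"xllcorner {grid.spec.xmin!r}\n")
        fh.write(f"yllcorner {grid.spec.ymin!r}\n")
        fh.write(f"cellsize {grid.spec.cell_size!r}\n")
        fh.write(f"NODATA_value {_NODATA!r}\n")
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path, crs: str = "local", name: str = "") -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    vals = vals.reshape(nrows, ncols)
    nodata = header.get("nodata_value", _NODATA)
    mask = vals == nodata
    vals = np.where(mask, np.nan, vals)
    spec = GridSpec(crs=crs, cell_size=header["cellsize"],
                    xmin=header["xllcorner"],
                    ymax=header["yllcorner"] + nrows * header["cellsize"],
                    nrows=nrows, ncols=ncols)
    return RasterGrid(spec, vals, mask, name)


def spec_to_dict(spec: GridSpec) -> dict:
    return dataclasses.asdict(spec)


def spec_from_dict(d: Mapping) -> GridSpec:
    return GridSpec(**dict(d))
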