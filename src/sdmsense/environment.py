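"""Environmental covariate stacks on a common regular grid.

The training region of a presence–background niche model is defined by the
cells of a raster stack: each layer is one covariate (e.g. a bioclimatic
variable), all layers share one grid, and a boolean validity mask marks the
cells that carry data in every layer.  Extent masks narrow the training
region (the cells that supply background conditions) without touching the
projection region, which is how a model trained on a well-surveyed
sub-region can still be projected onto the full map.

Rasters are read and written as single-band ESRI ASCII grids; extent
polygons as GeoJSON geometries rasterized by cell-center containment.
Reprojection is deliberately out of scope: layers on different geometries
are an error, never a resampling trigger.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import shapely

from .exceptions import AlignmentError, DegenerateExtentError

__all__ = [
    "GridSpec",
    "EnvStack",
    "ExtentMask",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_env_stack",
    "mask_extent",
    "extract_covariates",
    "sample_background",
    "extent_from_polygon",
]

#: tolerance for declaring two grid geometries identical
_GRID_ATOL = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid with square cells.

    Row 0 is the northernmost row.  Cell ``(r, c)`` spans
    ``x ∈ [x_origin + c·s, x_origin + (c+1)·s)`` and
    ``y ∈ (y_origin − (r+1)·s, y_origin − r·s]`` with ``s = cell_size``:
    intervals are half-open so a point on a shared edge belongs to the cell
    to its east/south.
    """

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    cell_size: float
    crs_label: str = "planar-synthetic"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def compatible(self, other: "GridSpec") -> bool:
        """True when all five numeric geometry fields agree within 1e-9."""
        mine = (self.n_rows, self.n_cols, self.x_origin, self.y_origin, self.cell_size)
        theirs = (other.n_rows, other.n_cols, other.x_origin, other.y_origin, other.cell_size)
        return bool(np.allclose(mine, theirs, rtol=0.0, atol=_GRID_ATOL))

    def cell_of(self, x, y):
        """Raw (row, col) floor indices of the cells containing points.

        Indices are *not* clipped to the grid: callers that need bounds
        checking compare against ``shape`` (see :func:`extract_covariates`).
        Vectorized over array inputs.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_origin) / self.cell_size).astype(np.int64)
        # floor((y_origin - y)/s) lands a shared horizontal edge in the cell
        # to its south; the grid's own north edge (y == y_origin) in row 0.
        row = np.floor((self.y_origin - y) / self.cell_size).astype(np.int64)
        return row, col

    def cell_centers(self):
        """(x, y) center coordinates as two 2-D arrays of grid shape."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        cx = self.x_origin + (cols + 0.5) * self.cell_size
        cy = self.y_origin - (rows + 0.5) * self.cell_size
        return np.meshgrid(cx, cy)


@dataclass
class EnvStack:
    """A named set of covariate layers on one grid with a shared validity mask."""

    grid: GridSpec
    layer_names: list[str]
    values: np.ndarray  # (n_layers, n_rows, n_cols) float
    valid_mask: np.ndarray  # (n_rows, n_cols) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValueError("layer names must be unique")
        expected = (len(self.layer_names), self.grid.n_rows, self.grid.n_cols)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if self.valid_mask.shape != self.grid.shape:
            raise ValueError("valid_mask shape does not match grid")
        if not np.all(np.isfinite(self.values[:, self.valid_mask])):
            raise ValueError("non-finite covariate values inside the valid mask")

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def layer(self, name: str) -> np.ndarray:
        return self.values[self.layer_names.index(name)]

    def valid_table(self) -> pd.DataFrame:
        """Covariates of every valid cell, indexed by (row, col)."""
        rr, cc = np.nonzero(self.valid_mask)
        data = {name: self.values[i, rr, cc] for i, name in enumerate(self.layer_names)}
        out = pd.DataFrame(data)
        out.insert(0, "row", rr)
        out.insert(1, "col", cc)
        return out


@dataclass
class ExtentMask:
    """A labeled boolean region on a grid (e.g. 'full' vs 'restricted')."""

    grid: GridSpec
    inside: np.ndarray
    label: str = "extent"

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.shape != self.grid.shape:
            raise ValueError("extent mask shape does not match grid")
        if not self.inside.any():
            raise DegenerateExtentError(f"extent '{self.label}' contains no cells")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

def read_ascii_grid(path) -> tuple[GridSpec, np.ndarray, np.ndarray]:
    """Read a single-band ESRI ASCII grid.

    Returns ``(grid, values, data_mask)`` where nodata cells (per the header's
    NODATA_value) are NaN in ``values`` and False in ``data_mask``.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        n_header = 0
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                fh.seek(pos)
                break
        body = np.loadtxt(fh, dtype=float, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise AlignmentError(f"{path}: missing required header field '{key}'")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if body.shape != (n_rows, n_cols):
        raise AlignmentError(f"{path}: body shape {body.shape} != header ({n_rows}, {n_cols})")
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
    )
    mask = np.ones(body.shape, dtype=bool)
    if "nodata_value" in header:
        mask = body != header["nodata_value"]
    values = np.where(mask, body, np.nan)
    return grid, values, mask


def write_ascii_grid(path, grid: GridSpec, values: np.ndarray, nodata: float = -9999.0) -> None:
    """Write one layer as an ESRI ASCII grid; NaN cells become ``nodata``."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("layer shape does not match grid")
    body = np.where(np.isfinite(values), values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {grid.y_origin - grid.n_rows * grid.cell_size!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in body:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_env_stack(paths, names=None) -> EnvStack:
    """Read several single-band rasters into one stack.

    The stack's validity mask is the intersection of the per-layer data
    masks; layer order follows input order.  Layers on mismatched grid
    geometries raise :class:`AlignmentError` naming the offending layer.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("at least one raster path is required")
    if names is None:
        import os

        names = [os.path.splitext(os.path.basename(str(p)))[0] for p in paths]
    if len(names) != len(paths):
        raise ValueError("names and paths must have equal length")

    grid = None
    layers, mask = [], None
    for path, name in zip(paths, names):
        g, vals, m = read_ascii_grid(path)
        if grid is None:
            grid, mask = g, m
        elif not grid.compatible(g):
            raise AlignmentError(f"layer '{name}' ({path}) is not aligned with the first layer")
        else:
            mask = mask & m
        layers.append(vals)
    values = np.stack(layers, axis=0)
    values = np.where(mask[None, :, :], values, np.nan)
    return EnvStack(grid=grid, layer_names=list(names), values=values, valid_mask=mask)


# ---------------------------------------------------------------------------
# Extent handling

def mask_extent(stack: EnvStack, extent: ExtentMask) -> EnvStack:
    """Intersect a stack's validity mask with an extent.

    Values are untouched, so the result can serve as a training region while
    the original stack remains the projection region.
    """
    if not stack.grid.compatible(extent.grid):
        raise AlignmentError("extent grid is not compatible with the stack grid")
    new_mask = stack.valid_mask & extent.inside
    if not new_mask.any():
        raise DegenerateExtentError(
            f"extent '{extent.label}' leaves no valid cells in the stack"
        )
    return replace(stack, valid_mask=new_mask)


def extent_from_polygon(geometry, grid: GridSpec, label: str = "polygon") -> ExtentMask:
    """Rasterize a (Geo)JSON geometry or shapely geometry by cell-center containment."""
    if isinstance(geometry, (str, bytes)):
        geometry = json.loads(geometry)
    if isinstance(geometry, dict):
        if geometry.get("type") == "Feature":
            geometry = geometry["geometry"]
        geom = shapely.geometry.shape(geometry)
    else:
        geom = geometry
    cx, cy = grid.cell_centers()
    inside = shapely.contains_xy(geom, cx.ravel(), cy.ravel()).reshape(grid.shape)
    return ExtentMask(grid=grid, inside=inside, label=label)


# ---------------------------------------------------------------------------
# Point extraction and background sampling

def extract_covariates(stack: EnvStack, points) -> pd.DataFrame:
    """Look up the covariates of the cells containing each point.

    Points outside the grid or on invalid cells are flagged (``valid`` False)
    rather than dropped, so callers can account for every input record.
    """
    pts = np.asarray(list(points), dtype=float).reshape(-1, 2)
    n = pts.shape[0]
    out = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1]})
    if n == 0:
        for name in stack.layer_names:
            out[name] = np.array([], dtype=float)
        out["row"] = np.array([], dtype=np.int64)
        out["col"] = np.array([], dtype=np.int64)
        out["valid"] = np.array([], dtype=bool)
        return out
    row, col = stack.grid.cell_of(pts[:, 0], pts[:, 1])
    in_bounds = (row >= 0) & (row < stack.grid.n_rows) & (col >= 0) & (col < stack.grid.n_cols)
    r_safe = np.clip(row, 0, stack.grid.n_rows - 1)
    c_safe = np.clip(col, 0, stack.grid.n_cols - 1)
    valid = in_bounds & stack.valid_mask[r_safe, c_safe]
    for i, name in enumerate(stack.layer_names):
        vals = stack.values[i, r_safe, c_safe]
        out[name] = np.where(valid, vals, np.nan)
    out["row"] = row
    out["col"] = col
    out["valid"] = valid
    return out


def sample_background(stack: EnvStack, n: int, seed: int):
    """Draw background (pseudo-absence) cells uniformly without replacement.

    Returns ``(cells, table)`` where ``cells`` is an (k, 2) array of
    (row, col) indices and ``table`` their covariates.  When ``n`` meets or
    exceeds the number of valid cells, every valid cell is returned exactly
    once.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("background size must be at least 1")
    rr, cc = np.nonzero(stack.valid_mask)
    n_valid = rr.size
    if n_valid == 0:
        raise DegenerateExtentError("stack has no valid cells to sample background from")
    if n >= n_valid:
        idx = np.arange(n_valid)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n_valid, size=n, replace=False)
    cells = np.column_stack([rr[idx], cc[idx]])
    data = {
        name: stack.values[i, cells[:, 0], cells[:, 1]]
        for i, name in enumerate(stack.layer_names)
    }
    table = pd.DataFrame(data)
    table.insert(0, "row", cells[:, 0])
    table.insert(1, "col", cells[:, 1])
    return cells, table
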