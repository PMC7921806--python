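"""Georeferenced elevation grids and the crop surface model (CSM).

A digital terrain model (DTM, bare soil) and per-flight digital surface
models (DSM, soil + canopy) are single-band elevation rasters.  Their
cellwise difference, the crop surface model ``CSM = DSM - DTM``, is the
per-cell canopy height above ground from which plot-level plant height is
extracted.

Conventions used throughout the package (one rule everywhere):

* pixel-is-area, north-up grids: origin at the top-left *corner*, positive
  cell width ``dx``, negative cell height ``dy``;
* half-open cells: a point lying exactly on a shared edge belongs to the
  cell to its lower-right.

Rasters are stored as single-band float64 GeoTIFF with the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA), written
and parsed with :mod:`tifffile`.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import tifffile

__all__ = [
    "GridTransform",
    "ElevationGrid",
    "GridAlignment",
    "TargetSample",
    "read_elevation_raster",
    "write_elevation_raster",
    "compute_csm",
    "sample_target_height",
]

DEFAULT_NODATA = -9999.0

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class RasterFormatError(ValueError):
    """File is not a single-band georeferenced raster."""


class GridAlignmentError(ValueError):
    """Grids do not satisfy the requested alignment policy."""


@dataclass(frozen=True)
class GridTransform:
    """North-up affine geotransform (no rotation, square or rectangular cells).

    ``x0, y0`` is the world coordinate of the top-left corner of pixel
    (0, 0); ``dx > 0`` and ``dy < 0`` are the cell sizes in world units.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy < 0):
            raise ValueError("north-up transform requires dx > 0 and dy < 0")

    def cell_center(self, row, col):
        """World (x, y) of the center of cell(s) (row, col)."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.dx
        y = self.y0 + (np.asarray(row) + 0.5) * self.dy
        return x, y

    def world_to_cell(self, x, y):
        """Cell indices (row, col) containing world points.

        Half-open rule: a point on a shared edge belongs to the cell to its
        lower-right (larger col / larger row).
        """
        col = np.floor((np.asarray(x, dtype=float) - self.x0) / self.dx).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - self.y0) / self.dy).astype(int)
        return row, col

    def bounds(self, shape):
        """(xmin, ymin, xmax, ymax) of a raster of the given shape."""
        nrow, ncol = shape
        return (
            self.x0,
            self.y0 + nrow * self.dy,
            self.x0 + ncol * self.dx,
            self.y0,
        )

    def almost_equals(self, other: "GridTransform", tol: float = 1e-9) -> bool:
        return (
            math.isclose(self.x0, other.x0, abs_tol=tol)
            and math.isclose(self.y0, other.y0, abs_tol=tol)
            and math.isclose(self.dx, other.dx, rel_tol=0, abs_tol=tol)
            and math.isclose(self.dy, other.dy, rel_tol=0, abs_tol=tol)
        )


@dataclass
class ElevationGrid:
    """A single-band georeferenced elevation array (meters)."""

    values: np.ndarray
    transform: GridTransform
    nodata: float = DEFAULT_NODATA
    crs_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a nonempty 2D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.transform.bounds(self.shape)

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        valid = self.values != self.nodata
        return valid & np.isfinite(self.values)

    def cell_centers(self):
        """Meshgrid-free center coordinates: (x of cols, y of rows)."""
        nrow, ncol = self.shape
        x = self.transform.x0 + (np.arange(ncol) + 0.5) * self.transform.dx
        y = self.transform.y0 + (np.arange(nrow) + 0.5) * self.transform.dy
        return x, y


@dataclass(frozen=True)
class GridAlignment:
    """How to bring a second grid onto the grid of the first.

    ``exact`` (default) requires identical transforms and shapes; ``snap``
    resamples nearest-neighbor; ``bilinear`` interpolates.  Exact-by-default
    because silent resampling hides georeferencing bugs.
    """

    policy: Literal["exact", "snap", "bilinear"] = "exact"

    def __post_init__(self) -> None:
        if self.policy not in ("exact", "snap", "bilinear"):
            raise ValueError(f"unknown alignment policy {self.policy!r}")


def write_elevation_raster(path: str | os.PathLike, grid: ElevationGrid) -> None:
    """Write a grid as single-band float64 GeoTIFF (nodata default -9999).

    Double precision keeps the zero-noise simulation identity exact through
    a disk round trip; the format is otherwise plain GeoTIFF.
    """
    t = grid.transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.dx, -t.dy, 0.0), True),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0), True),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(grid.nodata)), True),
    ]
    tifffile.imwrite(
        path,
        grid.values.astype(np.float64),
        photometric="minisblack",
        description=grid.crs_label,
        extratags=extratags,
    )


def read_elevation_raster(path: str | os.PathLike) -> ElevationGrid:
    """Read a single-band georeferenced GeoTIFF written by this package.

    Raises ``FileNotFoundError`` for a missing file and
    :class:`RasterFormatError` for multi-band or non-georeferenced input.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise RasterFormatError(f"{path}: expected single band, got {page.samplesperpixel}")
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise RasterFormatError(f"{path}: missing georeferencing tags")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_MODEL_TIEPOINT].value
        # tiepoint maps raster (i, j, k) -> world (x, y, z); we require (0, 0)
        if tie[0] != 0 or tie[1] != 0:
            raise RasterFormatError(f"{path}: unsupported tiepoint anchor {tie[:2]}")
        x0, y0 = tie[3], tie[4]
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
        crs_label = ""
        if 270 in tags:  # ImageDescription
            crs_label = str(tags[270].value)
        values = page.asarray()
    return ElevationGrid(
        values=values,
        transform=GridTransform(x0=x0, y0=y0, dx=float(sx), dy=-float(sy)),
        nodata=nodata,
        crs_label=crs_label,
    )


def _resample_onto(
    src: ElevationGrid, ref: ElevationGrid, method: Literal["snap", "bilinear"]
) -> np.ndarray:
    """Resample ``src`` onto ``ref``'s grid; cells outside src become nodata."""
    xs, ys = ref.cell_centers()
    X, Y = np.meshgrid(xs, ys)
    out = np.full(ref.shape, src.nodata, dtype=np.float64)
    if method == "snap":
        row, col = src.transform.world_to_cell(X, Y)
        inside = (row >= 0) & (row < src.shape[0]) & (col >= 0) & (col < src.shape[1])
        out[inside] = src.values[row[inside], col[inside]]
    else:  # bilinear on cell centers; any nodata neighbor poisons the cell
        t = src.transform
        nrow, ncol = src.shape
        fc = (X - t.x0) / t.dx - 0.5
        fr = (Y - t.y0) / t.dy - 0.5
        # points within half a cell of the border clamp to the edge value
        inside = (fr >= -0.5) & (fr <= nrow - 0.5) & (fc >= -0.5) & (fc <= ncol - 0.5)
        frc = np.clip(fr, 0.0, nrow - 1.0)
        fcc = np.clip(fc, 0.0, ncol - 1.0)
        r0 = np.minimum(np.floor(frc).astype(int), nrow - 2) if nrow > 1 else np.zeros_like(frc, int)
        c0 = np.minimum(np.floor(fcc).astype(int), ncol - 2) if ncol > 1 else np.zeros_like(fcc, int)
        wr = frc - r0
        wc = fcc - c0
        r0c = np.clip(r0, 0, max(nrow - 2, 0))
        c0c = np.clip(c0, 0, max(ncol - 2, 0))
        v00 = src.values[r0c, c0c]
        v01 = src.values[r0c, c0c + 1]
        v10 = src.values[r0c + 1, c0c]
        v11 = src.values[r0c + 1, c0c + 1]
        valid = inside
        for v in (v00, v01, v10, v11):
            valid = valid & (v != src.nodata)
        interp = (
            v00 * (1 - wr) * (1 - wc)
            + v01 * (1 - wr) * wc
            + v10 * wr * (1 - wc)
            + v11 * wr * wc
        )
        out[valid] = interp[valid]
    return out


def compute_csm(
    dsm: ElevationGrid,
    dtm: ElevationGrid,
    alignment: GridAlignment = GridAlignment("exact"),
    clamp_negative: bool = False,
) -> ElevationGrid:
    """Crop surface model: cellwise ``DSM - DTM`` on the DSM's grid.

    Nodata in either input propagates to the output.  Negative heights are
    kept by default (they diagnose terrain-model error); ``clamp_negative``
    sets them to zero.
    """
    b1 = dsm.bounds
    b2 = dtm.bounds
    if b1[0] >= b2[2] or b2[0] >= b1[2] or b1[1] >= b2[3] or b2[1] >= b1[3]:
        raise GridAlignmentError("DSM and DTM do not overlap spatially")
    if alignment.policy == "exact":
        if dsm.shape != dtm.shape or not dsm.transform.almost_equals(dtm.transform):
            raise GridAlignmentError(
                "grids differ under 'exact' policy; pass snap/bilinear to resample"
            )
        dtm_vals = dtm.values
        dtm_valid = dtm.mask()
    else:
        dtm_vals = _resample_onto(dtm, dsm, alignment.policy)
        dtm_valid = dtm_vals != dtm.nodata
    valid = dsm.mask() & dtm_valid
    out = np.full(dsm.shape, DEFAULT_NODATA, dtype=np.float64)
    diff = dsm.values[valid].astype(np.float64) - dtm_vals[valid].astype(np.float64)
    if clamp_negative:
        diff = np.maximum(diff, 0.0)
    out[valid] = diff
    return ElevationGrid(out, dsm.transform, nodata=DEFAULT_NODATA, crs_label=dsm.crs_label)


@dataclass
class TargetSample:
    """Robust CSM height at a ground target's footprint."""

    target_id: str
    height_m: float
    n_cells: int
    ok: bool
    reason: str = ""


def sample_target_height(
    csm: ElevationGrid, x: float, y: float, footprint_m: float = 0.2, target_id: str = ""
) -> TargetSample:
    """Median CSM height over a square footprint centered at (x, y).

    Cells are included when their centers fall inside the half-open square
    (module-wide center rule).  The median is robust to edge cells that
    straddle a pillar wall.  An all-nodata or empty footprint yields a
    flagged missing value.
    """
    half = footprint_m / 2.0
    t = csm.transform
    r0, c0 = t.world_to_cell(x - half, y + half)
    r1, c1 = t.world_to_cell(x + half, y - half)
    r0 = max(int(r0), 0)
    c0 = max(int(c0), 0)
    r1 = min(int(r1), csm.shape[0] - 1)
    c1 = min(int(c1), csm.shape[1] - 1)
    if r1 < r0 or c1 < c0:
        return TargetSample(target_id, float("nan"), 0, False, "outside raster")
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    cx, cy = t.cell_center(rows[:, None], cols[None, :])
    inside = (
        (cx >= x - half) & (cx < x + half) & (cy > y - half) & (cy <= y + half)
    )
    block = csm.values[r0 : r1 + 1, c0 : c1 + 1]
    valid = inside & (block != csm.nodata) & np.isfinite(block)
    vals = block[valid]
    if vals.size == 0:
        return TargetSample(target_id, float("nan"), 0, False, "footprint entirely nodata")
    return TargetSample(target_id, float(np.median(vals)), int(vals.size), True)
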