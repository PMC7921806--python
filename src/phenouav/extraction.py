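"""Buffered plot ROIs and the per-plot plant-height statistic.

Each plot polygon is shrunk inward by a buffer (default 0.10 m) to keep
only pure within-plot pixels, the crop surface model is sampled at cell
centers inside the shrunken polygon, and the sample is reduced to a single
plant height — by default the mean of the pixels above the sample's 75th
percentile, which tracks the canopy top while discarding furrow and leaf-
flank pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .grids import ElevationGrid
from .trial import FieldLayout, HEIGHT_COLUMNS

__all__ = [
    "PlotROI",
    "PixelSample",
    "STATISTICS",
    "build_rois",
    "extract_pixels",
    "plot_height",
    "extract_trial",
]

STATISTICS = ("mean_above_p75", "mean", "median", "p90", "p95", "p99")

DEFAULT_BUFFER_M = 0.10
DEFAULT_MIN_PIXELS = 30


class BufferError(ValueError):
    """Inward buffering collapsed one or more plot polygons."""

    def __init__(self, plot_ids: list[str]):
        self.plot_ids = plot_ids
        super().__init__(f"buffer collapses plots: {', '.join(plot_ids)}")


@dataclass
class PlotROI:
    plot_id: str
    polygon: Polygon  # inward-buffered region the pixels come from
    source_polygon: Polygon
    buffer_m: float


@dataclass
class PixelSample:
    plot_id: str
    values: np.ndarray  # meters, nodata already excluded

    @property
    def n_pixels(self) -> int:
        return int(self.values.size)


def build_rois(layout: FieldLayout, buffer_m: float = DEFAULT_BUFFER_M) -> list[PlotROI]:
    """Inward-buffer every plot polygon by ``buffer_m`` (mitred corners).

    Raises :class:`BufferError` naming every plot whose polygon collapses.
    """
    if buffer_m < 0:
        raise ValueError("buffer_m must be >= 0")
    rois = []
    collapsed = []
    for plot in layout:
        if buffer_m == 0:
            inner = plot.polygon
        else:
            inner = plot.polygon.buffer(-buffer_m, join_style="mitre")
        if inner.is_empty or inner.area <= 0:
            collapsed.append(plot.plot_id)
            continue
        rois.append(
            PlotROI(
                plot_id=plot.plot_id,
                polygon=inner,
                source_polygon=plot.polygon,
                buffer_m=buffer_m,
            )
        )
    if collapsed:
        raise BufferError(collapsed)
    return rois


def extract_pixels(csm: ElevationGrid, roi: PlotROI) -> PixelSample:
    """All valid CSM values whose cell centers lie strictly inside the ROI.

    Strict interiority (shapely ``contains``) matches the package-wide
    center rule; nodata cells are dropped.  A ROI outside the raster yields
    an empty sample for the caller to flag.
    """
    t = csm.transform
    xmin, ymin, xmax, ymax = roi.polygon.bounds
    r0, c0 = t.world_to_cell(xmin, ymax)
    r1, c1 = t.world_to_cell(xmax, ymin)
    r0, c0 = max(int(r0), 0), max(int(c0), 0)
    r1, c1 = min(int(r1), csm.shape[0] - 1), min(int(c1), csm.shape[1] - 1)
    if r1 < r0 or c1 < c0:
        return PixelSample(roi.plot_id, np.empty(0, dtype=np.float64))
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    cx = t.x0 + (cols + 0.5) * t.dx
    cy = t.y0 + (rows + 0.5) * t.dy
    X, Y = np.meshgrid(cx, cy)
    inside = shapely.contains_xy(roi.polygon, X.ravel(), Y.ravel()).reshape(X.shape)
    block = csm.values[r0 : r1 + 1, c0 : c1 + 1]
    valid = inside & (block != csm.nodata) & np.isfinite(block)
    return PixelSample(roi.plot_id, block[valid].astype(np.float64, copy=True))


def plot_height(
    sample: PixelSample,
    statistic: str = "mean_above_p75",
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> tuple[float, str]:
    """Reduce a pixel sample to one plant height in centimeters.

    ``mean_above_p75``: mean of the values strictly greater than the
    sample's 75th percentile (linear-interpolation definition).  When no
    value strictly exceeds the threshold (ties at the top, e.g. a constant
    sample) the mean of the values equal to the threshold is returned
    instead of a missing value.

    Returns ``(value_cm, flag)``; flag is "" for a clean value,
    "too_few_pixels" or "empty" for a NaN result.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    v = sample.values
    if v.size == 0:
        return float("nan"), "empty"
    if v.size < min_pixels:
        return float("nan"), "too_few_pixels"
    if statistic == "mean":
        m = float(np.mean(v))
    elif statistic == "median":
        m = float(np.median(v))
    elif statistic.startswith("p"):
        m = float(np.percentile(v, float(statistic[1:])))
    else:  # mean_above_p75
        q = np.percentile(v, 75.0)
        upper = v[v > q]
        if upper.size == 0:
            upper = v[v == q]
        m = float(np.mean(upper))
    return m * 100.0, ""


def extract_trial(
    csm_by_stage: dict[str, ElevationGrid],
    rois: list[PlotROI],
    layout: FieldLayout,
    statistic: str = "mean_above_p75",
    platform: str = "aerial",
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> pd.DataFrame:
    """One height row per plot x stage; errors carried in the ``flag`` column.

    Ordering is stable (stage in input order, then plot_id) and the output
    is reproducible bit-for-bit on identical inputs.
    """
    attrs = layout.frame()
    rows = []
    for stage, csm in csm_by_stage.items():
        for roi in sorted(rois, key=lambda r: r.plot_id):
            sample = extract_pixels(csm, roi)
            value, flag = plot_height(sample, statistic, min_pixels)
            meta = attrs.loc[roi.plot_id]
            rows.append(
                {
                    "plot_id": roi.plot_id,
                    "genotype": meta.genotype,
                    "rep": int(meta.rep),
                    "block": int(meta.block),
                    "stage": stage,
                    "platform": platform,
                    "ph_cm": value,
                    "n_pixels": sample.n_pixels,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows, columns=HEIGHT_COLUMNS + ["n_pixels", "flag"])
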