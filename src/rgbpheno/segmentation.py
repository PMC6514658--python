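"""Plot extraction from orthomosaics and batch indexing.

A field trial's aerial orthomosaic is cut into one micro-image per plot
using a table of axis-aligned rectangular regions of interest (ROIs).
Coordinates are 0-based, half-open pixel rectangles [x0, x1) × [y0, y1),
matching raster indexing, so cropping then indexing is pixel-exact
equivalent to indexing a pre-cropped image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .color import RgbImage, read_image
from .indices import PlotIndexRecord, summarize_plot

__all__ = ["PlotROI", "read_rois", "crop_plots", "batch_index"]

log = logging.getLogger(__name__)

ROI_COLUMNS = ["plot_id", "x0", "y0", "x1", "y1", "genotype", "replicate", "treatment"]


@dataclass
class PlotROI:
    """One plot's rectangle on the mosaic plus its trial identity."""

    plot_id: str
    x0: int
    y0: int
    x1: int
    y1: int
    genotype: str = ""
    replicate: int = 0
    treatment: str = ""

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(
                f"ROI {self.plot_id}: needs x1 > x0 and y1 > y0, "
                f"got ({self.x0},{self.y0},{self.x1},{self.y1})"
            )


def read_rois(path: str | Path) -> list[PlotROI]:
    """Read a plot-ROI table (CSV with columns plot_id,x0,y0,x1,y1,...)."""
    df = pd.read_csv(path)
    missing = [c for c in ("plot_id", "x0", "y0", "x1", "y1") if c not in df.columns]
    if missing:
        raise ValueError(f"ROI table missing columns: {missing}")
    rois = []
    for row in df.itertuples(index=False):
        rois.append(
            PlotROI(
                plot_id=str(row.plot_id),
                x0=int(row.x0), y0=int(row.y0), x1=int(row.x1), y1=int(row.y1),
                genotype=str(getattr(row, "genotype", "")),
                replicate=int(getattr(row, "replicate", 0) or 0),
                treatment=str(getattr(row, "treatment", "")),
            )
        )
    return rois


def crop_plots(mosaic: RgbImage, rois: list[PlotROI]) -> list[tuple[str, RgbImage]]:
    """Cut one micro-image per ROI, order preserved, pixel-exact.

    Raises on the first out-of-bounds ROI (naming the plot) and on
    duplicate plot ids.
    """
    h, w = mosaic.shape
    seen: set[str] = set()
    out: list[tuple[str, RgbImage]] = []
    for roi in rois:
        if roi.plot_id in seen:
            raise ValueError(f"duplicate plot_id {roi.plot_id!r} in ROI table")
        seen.add(roi.plot_id)
        if roi.x0 < 0 or roi.y0 < 0 or roi.x1 > w or roi.y1 > h:
            raise ValueError(
                f"ROI {roi.plot_id!r} out of mosaic bounds "
                f"({w}x{h}): ({roi.x0},{roi.y0},{roi.x1},{roi.y1})"
            )
        crop = mosaic.pixels[roi.y0:roi.y1, roi.x0:roi.x1].copy()
        out.append((roi.plot_id, RgbImage(crop, source_id=roi.plot_id)))
    return out


def batch_index(
    images: list[tuple[str, "RgbImage | str | Path"]],
    per_pixel_nd: bool = True,
) -> list[PlotIndexRecord]:
    """Index a batch of (plot_id, image-or-path) pairs.

    A plot that cannot be read or indexed yields a record with its
    ``error`` field set and all indices NaN; the batch continues. An empty
    batch is an input error.
    """
    if not images:
        raise ValueError("batch_index: empty image list")
    records: list[PlotIndexRecord] = []
    for plot_id, img in images:
        try:
            if not isinstance(img, RgbImage):
                img = read_image(img, source_id=plot_id)
            records.append(summarize_plot(img, plot_id=plot_id, per_pixel_nd=per_pixel_nd))
        except Exception as exc:  # noqa: BLE001 - per-plot failures must not kill the batch
            log.warning("plot %s failed: %s", plot_id, exc)
            records.append(PlotIndexRecord(plot_id=plot_id, error=str(exc)))
    return records
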