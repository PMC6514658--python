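"""Camera quality assurance: ColorChecker calibration check and vignetting.

Before using a consumer camera scientifically, two checks are run:

1. **Color calibration check** — a photographed 24-chip ColorChecker panel
   is compared channel-by-channel (R, G, B, L, a*, b*) against published
   chip values with ordinary least squares. High determination
   coefficients (R² ≥ 0.80) indicate color reproduction good enough to use
   the images uncalibrated; the toolkit reports quality but does not apply
   correction by default, since applying linear corrections tends to
   degrade index–yield relationships rather than improve them. An opt-in
   linear correction is provided.

2. **Vignetting transects** — on a high-altitude frame, digital numbers
   are extracted along the central row and column for R, G, B, hue, a*
   and b*, restricted by a hue-based filter to sunlit bare-soil pixels
   (vegetation and shadow excluded). Lens vignetting shows up as a gentle
   center-to-edge falloff in the RGB transects, while the
   lightness-separated a*/b* transects stay flat — the rationale for
   preferring CIELab/CIELuv chroma in index work.

The bundled chip reference (``data/colorchecker24_synthetic.csv``) is a
synthetic nominal table: the classic 24-patch sRGB coordinates in common
use, with Lab columns derived from those sRGB values under D65 by this
package. The regression check is invariant to affine re-specification of
the reference, so any published edition can be substituted via CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .color import RgbImage, color_planes, rgb_to_cielab
from .indices import GA_HUE_RANGE

__all__ = [
    "load_chip_reference",
    "measure_chip",
    "color_check",
    "apply_linear_correction",
    "vignetting_transects",
    "CalibrationReport",
    "SoilFilter",
]

CHANNELS = ["R", "G", "B", "L", "a_star", "b_star"]


def load_chip_reference(path: str | Path | None = None) -> pd.DataFrame:
    """Load the 24-chip reference table (bundled nominal values by default)."""
    if path is None:
        src = resources.files("rgbpheno.data") / "colorchecker24_synthetic.csv"
        with resources.as_file(src) as p:
            ref = pd.read_csv(p)
    else:
        ref = pd.read_csv(path)
    if ref["chip_id"].nunique() != 24 or len(ref) != 24:
        raise ValueError("chip reference must contain 24 unique chips")
    return ref


def measure_chip(img: RgbImage, roi: tuple[int, int, int, int]) -> tuple[float, float, float]:
    """Median R, G, B of a chip patch [x0,x1)×[y0,y1).

    The median is robust to specular pixels at patch edges.
    """
    x0, y0, x1, y1 = roi
    patch = img.pixels[y0:y1, x0:x1].reshape(-1, 3)
    if patch.size == 0:
        raise ValueError("empty chip patch")
    med = np.median(patch, axis=0)
    return float(med[0]), float(med[1]), float(med[2])


@dataclass
class CalibrationReport:
    """Per-channel OLS of measured vs reference chip values.

    ``table`` has one row per channel with slope, intercept, r2 and a
    ``flag`` column marking channels with R² < ``r2_threshold``.
    """

    table: pd.DataFrame
    r2_threshold: float = 0.80

    @property
    def flagged(self) -> list[str]:
        return list(self.table.loc[self.table["flag"], "channel"])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def plot(self, merged: pd.DataFrame | None = None, path: str | Path | None = None):
        """Optional per-channel measured-vs-reference scatter panel (PNG).

        ``merged`` is the chip table with ``<channel>_ref``/``<channel>_meas``
        columns as produced inside :func:`color_check`; without it only the
        fitted lines are drawn.
        """
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 3, figsize=(11, 7))
        for ax, (_, row) in zip(axes.ravel(), self.table.iterrows()):
            ch = row["channel"]
            if merged is not None:
                ax.scatter(merged[f"{ch}_ref"], merged[f"{ch}_meas"], s=18)
                x = np.linspace(merged[f"{ch}_ref"].min(),
                                merged[f"{ch}_ref"].max(), 10)
            else:
                x = np.linspace(0, 255 if ch in "RGB" else 100, 10)
            ax.plot(x, row["slope"] * x + row["intercept"], "k-")
            ax.plot(x, x, "k:", alpha=0.5)
            ax.set_title(f"{ch}: R$^2$={row['r2']:.3f}")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def _with_lab(df: pd.DataFrame) -> pd.DataFrame:
    """Ensure L/a*/b* columns exist, deriving them from R, G, B if absent."""
    df = df.copy()
    if not {"L", "a_star", "b_star"}.issubset(df.columns):
        rgb = df[["R", "G", "B"]].to_numpy(float).reshape(-1, 1, 3)
        planes = rgb_to_cielab(RgbImage(np.clip(np.round(rgb), 0, 255)))
        df["L"] = planes.L.ravel()
        df["a_star"] = planes.a_star.ravel()
        df["b_star"] = planes.b_star.ravel()
    return df


def color_check(
    measured: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    r2_threshold: float = 0.80,
) -> CalibrationReport:
    """Regress measured chip colors on the published reference, per channel.

    ``measured`` needs columns chip_id, R, G, B (L/a*/b* derived if
    absent); all 24 chips must be present, matched by chip_id.
    """
    if reference is None:
        reference = load_chip_reference()
    reference = _with_lab(reference)
    measured = _with_lab(measured)
    missing = sorted(set(reference["chip_id"]) - set(measured["chip_id"]))
    if missing:
        raise ValueError(f"missing measured chips: {missing}")
    merged = reference.merge(measured, on="chip_id", suffixes=("_ref", "_meas"))
    rows = []
    for ch in CHANNELS:
        x = merged[f"{ch}_ref"].to_numpy(float)
        y = merged[f"{ch}_meas"].to_numpy(float)
        fit = stats.linregress(x, y)
        r2 = fit.rvalue**2
        rows.append(
            dict(channel=ch, slope=fit.slope, intercept=fit.intercept,
                 r2=r2, flag=bool(r2 < r2_threshold))
        )
    return CalibrationReport(pd.DataFrame(rows), r2_threshold=r2_threshold)


def apply_linear_correction(img: RgbImage, report: CalibrationReport) -> RgbImage:
    """Opt-in: invert the fitted per-channel linear response on R, G, B.

    Maps measured DN back to the reference scale via (DN − intercept)/slope.
    Off by default because calibration typically reports high R² and
    correction has not been observed to improve index performance.
    """
    t = report.table.set_index("channel")
    out = img.pixels.astype(np.float64)
    for i, ch in enumerate(["R", "G", "B"]):
        slope = t.loc[ch, "slope"]
        if slope == 0:
            raise ValueError(f"channel {ch}: zero slope, cannot invert")
        out[..., i] = (out[..., i] - t.loc[ch, "intercept"]) / slope
    return RgbImage(np.clip(np.round(out), 0, 255), source_id=img.source_id)


@dataclass
class SoilFilter:
    """Hue/saturation/intensity gate selecting sunlit bare-soil pixels.

    Defaults: hue outside the vegetation window [60°, 180°), saturation
    above 0.1 (rejects achromatic/specular pixels) and intensity above 0.2
    (rejects shadow).
    """

    veg_hue_range: tuple[float, float] = GA_HUE_RANGE
    min_saturation: float = 0.10
    min_intensity: float = 0.20

    def mask(self, planes) -> np.ndarray:
        lo, hi = self.veg_hue_range
        not_veg = ~(planes.valid_mask & (planes.hue >= lo) & (planes.hue < hi))
        return (
            not_veg
            & (planes.saturation > self.min_saturation)
            & (planes.intensity > self.min_intensity)
        )


def vignetting_transects(
    img: RgbImage, soil_filter: SoilFilter | None = None
) -> dict[str, object]:
    """Central-row and central-column transects of R, G, B, hue, a*, b*.

    Only pixels passing the soil filter are retained (NaN elsewhere), so
    the transects trace albedo of a homogeneous surface across the frame.
    Returns ``{"x": DataFrame, "y": DataFrame, "soil_mask": ndarray}``;
    each frame has a ``position`` column and one column per plane. Warns
    when no pixel passes the filter.
    """
    soil_filter = soil_filter or SoilFilter()
    h, w = img.shape
    if h < 3 or w < 3:
        raise ValueError("image too small for center transects")
    planes = color_planes(img)
    soil = soil_filter.mask(planes)
    if not soil.any():
        warnings.warn("no pixels pass the soil filter; transects are empty",
                      stacklevel=2)

    px = img.pixels.astype(float)
    plane_arrays = {
        "R": px[..., 0], "G": px[..., 1], "B": px[..., 2],
        "hue": planes.hue, "a_star": planes.a_star, "b_star": planes.b_star,
    }
    cy, cx = h // 2, w // 2

    def _line(sel_row: bool) -> pd.DataFrame:
        if sel_row:
            keep = soil[cy, :]
            data = {"position": np.arange(w)}
            for name, arr in plane_arrays.items():
                data[name] = np.where(keep, arr[cy, :], np.nan)
        else:
            keep = soil[:, cx]
            data = {"position": np.arange(h)}
            for name, arr in plane_arrays.items():
                data[name] = np.where(keep, arr[:, cx], np.nan)
        return pd.DataFrame(data)

    return {"x": _line(True), "y": _line(False), "soil_mask": soil}
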