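"""Plot-level RGB vegetation indices.

One canopy image per plot is reduced to a row of index values:

* Green area (GA): fraction of pixels whose hue falls in [60°, 180°) —
  yellow through bluish green — a proxy for fractional vegetation cover.
* Greener green area (GGA): the stricter range [80°, 180°), excluding
  yellowish-green tones of partially stressed or senescent tissue.
* Crop senescence index: CSI = 100 × (GA − GGA)/GA, the relative share of
  yellowish vegetation.
* TGI, the triangular greenness index, proportional to the area of the
  triangle spanned by broadband red/green/blue reflectance at their
  approximate band centers 670/550/480 nm, a chlorophyll proxy.
* NGRDI = (G − R)/(G + R) on the green and red bands.
* NDLab and NDLuv, normalized-difference indices over the CIELab and
  CIELuv chromatic axes, built so that green vegetation scores high and
  red/brown soil or yellow chlorosis scores low:
  NDLab = ((1 − a*) − b*)/((1 − a*) + b*) + 1, and identically for u*, v*.

Reflectance here is the raw 8-bit digital number divided by 255 — no
radiometric calibration, matching how broadband camera values are used
in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .color import RgbImage, ColorPlanes, color_planes

__all__ = [
    "PlotIndexRecord",
    "green_area",
    "greener_green_area",
    "crop_senescence_index",
    "tgi",
    "tgi_band_coefficients",
    "ngrdi",
    "ndlab",
    "ndluv",
    "summarize_plot",
    "records_to_frame",
]

#: GA hue window (degrees, closed-left / open-right).
GA_HUE_RANGE = (60.0, 180.0)
#: GGA hue window.
GGA_HUE_RANGE = (80.0, 180.0)
#: Band centers (nm) assigned to the red, green and blue camera channels.
BAND_CENTERS_NM = (670.0, 550.0, 480.0)
#: Denominator guard for the per-pixel normalized differences.
ND_EPS = 1e-6


@dataclass
class PlotIndexRecord:
    """One row of plot-level index values; missing values are NaN.

    ``csi`` is NaN when GA = 0 (no vegetation means senescence share is
    undefined, not zero). ``error`` is set when batch processing could not
    index the plot at all.
    """

    plot_id: str
    ga: float = math.nan
    gga: float = math.nan
    csi: float = math.nan
    hue_mean: float = math.nan
    intensity_mean: float = math.nan
    saturation_mean: float = math.nan
    lightness_mean: float = math.nan
    a_mean: float = math.nan
    b_mean: float = math.nan
    u_mean: float = math.nan
    v_mean: float = math.nan
    ndlab: float = math.nan
    ndluv: float = math.nan
    tgi: float = math.nan
    ngrdi: float = math.nan
    error: str | None = None


def _hue_fraction(planes: ColorPlanes, lo: float, hi: float) -> float:
    if planes.hue is None:
        raise ValueError("hue plane not populated")
    n = planes.n_pixels
    if n == 0:
        raise ValueError("image contains no pixels")
    hue = planes.hue
    valid = planes.valid_mask
    inside = valid & (hue >= lo) & (hue < hi)
    # achromatic pixels stay in the denominator: they are scene pixels
    return float(inside.sum()) / n


def green_area(planes: ColorPlanes) -> float:
    """Fraction of pixels with defined hue in [60°, 180°)."""
    return _hue_fraction(planes, *GA_HUE_RANGE)


def greener_green_area(planes: ColorPlanes) -> float:
    """Fraction of pixels with defined hue in [80°, 180°)."""
    return _hue_fraction(planes, *GGA_HUE_RANGE)


def crop_senescence_index(ga: float, gga: float) -> float:
    """CSI = 100 × (GA − GGA)/GA, in percent; NaN when GA = 0."""
    if gga > ga + 1e-12:
        raise ValueError(f"GGA ({gga}) exceeds GA ({ga}); invariant violated")
    if not (0.0 <= gga and ga <= 1.0):
        raise ValueError("GA and GGA must lie in [0, 1]")
    if ga == 0:
        return math.nan
    return 100.0 * (ga - min(gga, ga)) / ga


def tgi_band_coefficients(
    centers_nm: tuple[float, float, float] = BAND_CENTERS_NM,
) -> tuple[float, float]:
    """Coefficients of the triangle-area formula for given band centers.

    The triangle area over bands (λ1, R1), (λ2, R2), (λ3, R3) expands to
    ±0.5 [(λ1 − λ3)(R1 − R2) − (λ1 − λ2)(R1 − R3)]; with the camera band
    centers 670/550/480 nm the two wavelength coefficients are
    λ1 − λ3 = 190 and λ1 − λ2 = 120.
    """
    l1, l2, l3 = centers_nm
    return (l1 - l3, l1 - l2)


def tgi(img: RgbImage, centers_nm: tuple[float, float, float] = BAND_CENTERS_NM) -> float:
    """Triangular greenness index from channel-mean reflectances.

    TGI = −0.5 [(λ1 − λ3) × (R670 − R550) − (λ1 − λ2) × (R670 − R480)],
    with red↔R670, green↔R550, blue↔R480 and reflectance = DN/255.
    Units are wavelength × reflectance (nm here).
    """
    rgbf = img.as_float()
    r670 = float(rgbf[..., 0].mean())
    r550 = float(rgbf[..., 1].mean())
    r480 = float(rgbf[..., 2].mean())
    c_gr, c_bl = tgi_band_coefficients(centers_nm)
    return -0.5 * (c_gr * (r670 - r550) - c_bl * (r670 - r480))


def ngrdi(img: RgbImage) -> float:
    """Normalized green–red difference, (R550 − R670)/(R550 + R670).

    NaN when both band means are zero (all-black image).
    """
    rgbf = img.as_float()
    r670 = float(rgbf[..., 0].mean())
    r550 = float(rgbf[..., 1].mean())
    if r550 + r670 == 0:
        return math.nan
    return (r550 - r670) / (r550 + r670)


def _normalized_difference(first: np.ndarray, second: np.ndarray,
                           per_pixel: bool, eps: float) -> float:
    """((1 − x) − y)/((1 − x) + y) + 1 averaged over pixels (or of means)."""
    if not per_pixel:
        first = np.array([np.nanmean(first)])
        second = np.array([np.nanmean(second)])
    num = (1.0 - first) - second
    den = (1.0 - first) + second
    ok = np.abs(den) >= eps
    if not ok.any():
        return math.nan
    return float(np.mean(num[ok] / den[ok]) + 1.0)


def ndlab(planes: ColorPlanes, per_pixel: bool = True, eps: float = ND_EPS) -> float:
    """NDLab = ((1 − a*) − b*)/((1 − a*) + b*) + 1.

    Evaluated per pixel and averaged by default (``per_pixel=False``
    evaluates the formula at the plot-mean a*/b* instead). Pixels with
    near-zero denominator are excluded; NaN when all pixels are excluded.
    Note the formula as printed is not strictly bounded by [−1, 1]: at
    a* = b* = 0 it evaluates to 2 and the denominator can change sign.
    The literal formula is implemented; see docs/methods.md.
    """
    if planes.a_star is None or planes.b_star is None:
        raise ValueError("a*/b* planes not populated")
    return _normalized_difference(planes.a_star, planes.b_star, per_pixel, eps)


def ndluv(planes: ColorPlanes, per_pixel: bool = True, eps: float = ND_EPS) -> float:
    """NDLuv = ((1 − u*) − v*)/((1 − u*) + v*) + 1 (see :func:`ndlab`)."""
    if planes.u_star is None or planes.v_star is None:
        raise ValueError("u*/v* planes not populated")
    return _normalized_difference(planes.u_star, planes.v_star, per_pixel, eps)


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean of angles in degrees, result in [0, 360); NaN if empty."""
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return math.nan
    rad = np.deg2rad(a)
    mean = np.mod(np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())), 360.0)
    return float(0.0 if mean >= 360.0 else mean)


def summarize_plot(img: RgbImage, plot_id: str | None = None,
                   per_pixel_nd: bool = True) -> PlotIndexRecord:
    """Compute the full plot-level index record for one image.

    Plane means (hue, a*, b*, u*, v*, ...) are plot means of per-pixel
    values; the hue mean is circular (mean of unit vectors) over pixels
    with defined hue.
    """
    planes = color_planes(img)
    ga = green_area(planes)
    gga = greener_green_area(planes)
    return PlotIndexRecord(
        plot_id=plot_id if plot_id is not None else img.source_id,
        ga=ga,
        gga=gga,
        csi=crop_senescence_index(ga, gga),
        hue_mean=circular_mean_deg(planes.hue[planes.valid_mask]),
        intensity_mean=float(planes.intensity.mean()),
        saturation_mean=float(planes.saturation.mean()),
        lightness_mean=float(planes.L.mean()),
        a_mean=float(planes.a_star.mean()),
        b_mean=float(planes.b_star.mean()),
        u_mean=float(planes.u_star.mean()),
        v_mean=float(planes.v_star.mean()),
        ndlab=ndlab(planes, per_pixel=per_pixel_nd),
        ndluv=ndluv(planes, per_pixel=per_pixel_nd),
        tgi=tgi(img),
        ngrdi=ngrdi(img),
    )


def records_to_frame(records: list[PlotIndexRecord]) -> pd.DataFrame:
    """Stack records into a DataFrame (one CSV row per plot; NaN → empty cell)."""
    return pd.DataFrame([asdict(r) for r in records])
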