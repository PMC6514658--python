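"""Color-space machinery for canopy image analysis.

Consumer RGB cameras record 8-bit sRGB. Hue-threshold vegetation indices
(GA, GGA, CSI) operate in the hue-saturation-intensity (HSI) space, where
hue traverses the visible spectrum as an angle in [0, 360) with red at 0°,
green at 120° and blue at 240°. The CIELab and CIELuv spaces separate
lightness L* from the chromatic axes (a*, b* respectively u*, v*), which is
what makes chroma-based indices robust to illumination and vignetting.

Conversions assume sRGB (IEC 61966-2-1) gamma decoding and the D65 white
point, with no chromatic adaptation or ICC-profile handling: consumer
cameras emit sRGB JPEGs by default and the indices are used uncalibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import color as skcolor

__all__ = [
    "RgbImage",
    "ColorPlanes",
    "read_image",
    "rgb_to_hsi",
    "rgb_to_cielab",
    "rgb_to_cieluv",
    "color_planes",
]


@dataclass
class RgbImage:
    """An 8-bit three-channel raster, channel order red/green/blue.

    Parameters
    ----------
    pixels : ndarray of shape (H, W, 3)
        Integer channel values in [0, 255].
    source_id : str
        Free-text plot/camera identifier carried through the pipeline.
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"expected an H x W x 3 raster, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def as_float(self) -> np.ndarray:
        """Channels scaled to [0, 1] (no gamma decoding)."""
        return self.pixels.astype(np.float64) / 255.0


@dataclass
class ColorPlanes:
    """Per-pixel color planes derived from one :class:`RgbImage`.

    ``hue`` is in degrees [0, 360) and only defined where ``valid_mask`` is
    true; achromatic pixels (saturation 0) carry an undefined-hue flag so
    they can never count as green. ``L`` is CIE lightness in [0, 100];
    ``a_star``/``b_star`` and ``u_star``/``v_star`` are the CIE 1976
    chromatic axes. Planes not produced by a given conversion are ``None``.
    """

    shape: tuple[int, int]
    hue: np.ndarray | None = None
    saturation: np.ndarray | None = None
    intensity: np.ndarray | None = None
    L: np.ndarray | None = None
    a_star: np.ndarray | None = None
    b_star: np.ndarray | None = None
    u_star: np.ndarray | None = None
    v_star: np.ndarray | None = None
    valid_mask: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    @property
    def n_pixels(self) -> int:
        return int(self.shape[0] * self.shape[1])


def read_image(path: str | Path, source_id: str | None = None) -> RgbImage:
    """Read a PNG/JPEG/TIFF file as an 8-bit RGB image.

    Images with an alpha channel are rejected: transparency has no meaning
    for a canopy photograph and silently dropping it would hide an upstream
    processing mistake.
    """
    path = Path(path)
    with Image.open(path) as im:
        if im.mode in ("RGBA", "LA", "PA"):
            raise ValueError(
                f"{path.name}: alpha channel not supported; flatten the image first"
            )
        rgb = im.convert("RGB")
        arr = np.asarray(rgb, dtype=np.uint8)
    return RgbImage(arr, source_id=source_id or path.stem)


def _check(img: RgbImage) -> np.ndarray:
    if not isinstance(img, RgbImage):
        img = RgbImage(np.asarray(img))
    return img.as_float()


def rgb_to_hsi(img: RgbImage) -> ColorPlanes:
    """Convert to hue/saturation/intensity planes.

    Hue uses the standard hexcone formulation (red 0°, green 120°, blue
    240°); intensity is mean(R, G, B)/255 and saturation is 1 − min/I,
    the classic HSI definitions. Saturation is exactly zero iff the pixel
    is achromatic (R = G = B), and such pixels have undefined hue
    (``valid_mask`` false).
    """
    rgbf = _check(img)
    r, g, b = rgbf[..., 0], rgbf[..., 1], rgbf[..., 2]
    mx = rgbf.max(axis=-1)
    mn = rgbf.min(axis=-1)
    delta = mx - mn
    valid = delta > 0

    hue = np.zeros(mx.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(valid, delta, 1.0)
        hr = np.mod((g - b) / d, 6.0)
        hg = (b - r) / d + 2.0
        hb = (r - g) / d + 4.0
    hue = np.select([mx == r, mx == g], [hr, hg], default=hb) * 60.0
    hue = np.mod(hue, 360.0)
    hue[~valid] = np.nan

    intensity = rgbf.mean(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        saturation = np.where(intensity > 0, 1.0 - mn / np.where(intensity > 0, intensity, 1.0), 0.0)
    saturation = np.clip(saturation, 0.0, 1.0)

    return ColorPlanes(
        shape=mx.shape,
        hue=hue,
        saturation=saturation,
        intensity=intensity,
        valid_mask=valid,
    )


def rgb_to_cielab(img: RgbImage) -> ColorPlanes:
    """Convert to CIELab planes (sRGB decoding, D65 white).

    L is in [0, 100] for in-gamut sRGB input; a* spans green (negative) to
    red (positive), b* blue (negative) to yellow (positive), on the CIE
    1976 scale.
    """
    rgbf = _check(img)
    lab = skcolor.rgb2lab(rgbf)
    return ColorPlanes(
        shape=rgbf.shape[:2],
        L=lab[..., 0],
        a_star=lab[..., 1],
        b_star=lab[..., 2],
        valid_mask=np.ones(rgbf.shape[:2], bool),
    )


def rgb_to_cieluv(img: RgbImage) -> ColorPlanes:
    """Convert to CIELuv planes (sRGB decoding, D65 white, CIE 1976 u'v')."""
    rgbf = _check(img)
    luv = skcolor.rgb2luv(rgbf)
    return ColorPlanes(
        shape=rgbf.shape[:2],
        L=luv[..., 0],
        u_star=luv[..., 1],
        v_star=luv[..., 2],
        valid_mask=np.ones(rgbf.shape[:2], bool),
    )


def color_planes(img: RgbImage) -> ColorPlanes:
    """All planes (HSI + Lab + Luv) from one image in a single object.

    The lightness reported is CIELab L*; HSI intensity remains a distinct
    plane because the two are listed as distinct plot variables.
    """
    hsi = rgb_to_hsi(img)
    lab = rgb_to_cielab(img)
    luv = rgb_to_cieluv(img)
    return ColorPlanes(
        shape=hsi.shape,
        hue=hsi.hue,
        saturation=hsi.saturation,
        intensity=hsi.intensity,
        L=lab.L,
        a_star=lab.a_star,
        b_star=lab.b_star,
        u_star=luv.u_star,
        v_star=luv.v_star,
        valid_mask=hsi.valid_mask,
    )


def srgb_to_linear(dn: np.ndarray) -> np.ndarray:
    """Decode sRGB-encoded values in [0, 1] to linear light."""
    dn = np.asarray(dn, dtype=np.float64)
    return np.where(dn <= 0.04045, dn / 12.92, ((dn + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(lin: np.ndarray) -> np.ndarray:
    """Encode linear-light values in [0, 1] to sRGB."""
    lin = np.asarray(lin, dtype=np.float64)
    return np.where(
        lin <= 0.0031308, lin * 12.92, 1.055 * np.clip(lin, 0, None) ** (1 / 2.4) - 0.055
    )
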