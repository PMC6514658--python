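"""Independent brute-force color-space oracles used by the tests.

Coded directly from the CIE 1976 definitions (sRGB decoding, D65 white,
2° observer), per pixel in plain Python/NumPy scalars, deliberately
independent of the package's conversion path.
"""

from __future__ import annotations

import numpy as np

# classic sRGB -> XYZ (D65, 2 deg) matrix
_M = np.array([
    [0.412453, 0.357580, 0.180423],
    [0.212671, 0.715160, 0.072169],
    [0.019334, 0.119193, 0.950227],
])
# published D65 tristimulus values (2 deg observer)
_WHITE = np.array([0.95047, 1.0, 1.08883])

# classic published CIE constants: (6/29)^3 ~ 0.008856, 1/(3 (6/29)^2) ~ 7.787,
# and 903.3 = (29/3)^3 rounded, as tabulated in the standard references
_EPS = 0.008856
_KAPPA_L = 903.3


def _decode(c: float) -> float:
    c = c / 255.0
    return c / 12.92 if c <= 0.04045 else ((c + 0.055) / 1.055) ** 2.4


def _xyz(r: float, g: float, b: float) -> np.ndarray:
    return _M @ np.array([_decode(r), _decode(g), _decode(b)])


def _f(t: float) -> float:
    return t ** (1.0 / 3.0) if t > _EPS else 7.787 * t + 16.0 / 116.0


def lab_pixel(r: float, g: float, b: float) -> tuple[float, float, float]:
    """CIE 1976 L*a*b* of one 8-bit sRGB pixel."""
    x, y, z = _xyz(r, g, b) / _WHITE
    fx, fy, fz = _f(x), _f(y), _f(z)
    return 116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)


def luv_pixel(r: float, g: float, b: float) -> tuple[float, float, float]:
    """CIE 1976 L*u*v* of one 8-bit sRGB pixel."""
    x, y, z = _xyz(r, g, b)
    xn, yn, zn = _WHITE
    yr = y / yn
    L = 116.0 * yr ** (1.0 / 3.0) - 16.0 if yr > _EPS else _KAPPA_L * yr
    denom = x + 15.0 * y + 3.0 * z
    denom_n = xn + 15.0 * yn + 3.0 * zn
    if denom == 0:
        return L, 0.0, 0.0
    up, vp = 4.0 * x / denom, 9.0 * y / denom
    upn, vpn = 4.0 * xn / denom_n, 9.0 * yn / denom_n
    return L, 13.0 * L * (up - upn), 13.0 * L * (vp - vpn)
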