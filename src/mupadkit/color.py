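"""Colour-space arithmetic on the smartphone readout's scales.

All channels are kept on the ranges the readout reports: R, G, B and
grayscale on 0–255, hue on 0–360 degrees, saturation and value on 0–100
percent.  Image libraries that use a half-scale hue (0–179) or unit-interval
saturation must be converted at the I/O boundary; everything inside the
package speaks these ranges.

Hue is an angular quantity: averaging it arithmetically biases any zone whose
colour straddles the 360→0 wrap, so :func:`circular_mean_hue` is the only
sanctioned way to average hue and achromatic pixels carry hue 0 by convention
(never NaN), so zone averages stay well defined.
"""

from __future__ import annotations

import numpy as np

from .errors import InputDomainError

#: ITU-R BT.601 luma weights — the default of the desktop image tool used for
#: manual measurements, adopted so manual/automatic comparisons are like-for-like.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


def _check_channel(value, name: str) -> float:
    v = float(value)
    if not np.isfinite(v) or v < 0 or v > 255:
        raise InputDomainError(f"{name} channel must lie in [0, 255], got {value!r}")
    return v


def rgb_to_hsv(r, g, b):
    """Convert one 8-bit RGB triple to (hue°, saturation %, value %).

    Standard hexcone model rescaled to hue 0–360, saturation/value 0–100.
    Achromatic inputs (r=g=b) return hue 0 and saturation 0.
    """
    rf, gf, bf = _check_channel(r, "r"), _check_channel(g, "g"), _check_channel(b, "b")
    mx = max(rf, gf, bf)
    mn = min(rf, gf, bf)
    delta = mx - mn
    v = mx / 255.0 * 100.0
    s = 0.0 if mx == 0 else delta / mx * 100.0
    if delta == 0:
        h = 0.0
    elif mx == rf:
        h = (60.0 * ((gf - bf) / delta)) % 360.0
    elif mx == gf:
        h = 60.0 * ((bf - rf) / delta + 2.0)
    else:
        h = 60.0 * ((rf - gf) / delta + 4.0)
    h = h % 360.0
    if h >= 360.0:  # float mod of a tiny negative can round to exactly 360
        h = 0.0
    return h, s, v


def hsv_to_rgb(h, s, v):
    """Inverse hexcone transform; returns real-valued RGB on 0–255.

    ``h`` in degrees (any real, wrapped mod 360), ``s``/``v`` in percent.
    No rounding: quantisation to 8 bits is a rendering/export concern.
    """
    hh = float(h) % 360.0
    sf = float(s) / 100.0
    vf = float(v) / 100.0
    if not (0.0 <= sf <= 1.0) or not (0.0 <= vf <= 1.0):
        raise InputDomainError("saturation and value must lie in [0, 100]")
    c = vf * sf
    x = c * (1.0 - abs((hh / 60.0) % 2.0 - 1.0))
    m = vf - c
    sector = int(hh // 60.0) % 6
    rp, gp, bp = [(c, x, 0), (x, c, 0), (0, c, x), (0, x, c), (x, 0, c), (c, 0, x)][sector]
    return ((rp + m) * 255.0, (gp + m) * 255.0, (bp + m) * 255.0)


def rgb_to_gray(r, g, b):
    """Luminance-weighted grayscale (BT.601 weights), real-valued on 0–255."""
    rf, gf, bf = _check_channel(r, "r"), _check_channel(g, "g"), _check_channel(b, "b")
    wr, wg, wb = GRAY_WEIGHTS
    return wr * rf + wg * gf + wb * bf


def circular_mean_hue(hues, weights=None):
    """Weighted circular mean of hue angles, in degrees on [0, 360).

    Computed as the atan2 of the weighted mean sine and cosine; this is the
    direction of the resultant vector and is equivariant under rotation of
    all inputs.
    """
    h = np.atleast_1d(np.asarray(hues, dtype=float))
    if h.size == 0:
        raise InputDomainError("circular_mean_hue requires at least one hue")
    if np.any((h < 0) | (h >= 360)):
        raise InputDomainError("hues must lie in [0, 360)")
    if weights is None:
        w = np.ones_like(h)
    else:
        w = np.atleast_1d(np.asarray(weights, dtype=float))
        if w.shape != h.shape or np.any(w < 0) or w.sum() <= 0:
            raise InputDomainError("weights must be nonnegative, match hues, and sum > 0")
    rad = np.deg2rad(h)
    sin_m = np.average(np.sin(rad), weights=w)
    cos_m = np.average(np.cos(rad), weights=w)
    mean = float(np.rad2deg(np.arctan2(sin_m, cos_m)) % 360.0)
    return 0.0 if mean >= 360.0 else mean


# ---------------------------------------------------------------------------
# vectorised image-wide variants (used by zone measurement and segmentation)

def rgb_to_hsv_array(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised hexcone conversion for an (..., 3) RGB array.

    Returns (h, s, v) float arrays on the 0–360 / 0–100 / 0–100 scales.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise InputDomainError("expected an (..., 3) RGB array")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    mx = arr.max(axis=-1)
    mn = arr.min(axis=-1)
    delta = mx - mn
    v = mx / 255.0 * 100.0
    safe_mx = np.where(mx == 0, 1.0, mx)
    s = np.where(mx == 0, 0.0, delta / safe_mx * 100.0)
    safe_d = np.where(delta == 0, 1.0, delta)
    h_r = (60.0 * ((g - b) / safe_d)) % 360.0
    h_g = 60.0 * ((b - r) / safe_d + 2.0)
    h_b = 60.0 * ((r - g) / safe_d + 4.0)
    h = np.select([delta == 0, mx == r, mx == g], [0.0, h_r, h_g], default=h_b) % 360.0
    h = np.where(h >= 360.0, 0.0, h)
    return h, s, v


def rgb_to_gray_array(rgb: np.ndarray) -> np.ndarray:
    """Vectorised BT.601 grayscale for an (..., 3) RGB array."""
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise InputDomainError("expected an (..., 3) RGB array")
    return arr @ np.asarray(GRAY_WEIGHTS)
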