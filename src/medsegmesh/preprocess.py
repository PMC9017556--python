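"""Intensity-domain preparation of CT/MR stacks.

CT-value mapping, window/level display transform, histogram equalization,
inter-slice trilinear interpolation, and the two-step denoising scheme used
for sequential tomographic images: a 1-D median filter along the slice axis
followed by 2-D weighted neighborhood averaging within each slice.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .errors import InsufficientSlicesError, InvalidParameterError, OutOfRangeError
from .volume import ImageVolume, SmoothingKernel, WindowSpec

log = logging.getLogger(__name__)


def ct_value(mu_x, mu_water):
    """CT value (Hounsfield-style) of attenuation ``mu_x`` relative to water.

    ``1000 * (mu_x - mu_water) / mu_water``: water maps to 0, zero
    attenuation (air-like) to -1000.
    """
    mu_water = np.asarray(mu_water, dtype=float)
    if np.any(mu_water <= 0):
        raise InvalidParameterError("water attenuation coefficient must be positive")
    return 1000.0 * (np.asarray(mu_x, dtype=float) - mu_water) / mu_water


def window_transform(img: ImageVolume, win: WindowSpec) -> ImageVolume:
    """Map CT values through a display window onto floating-point gray [0, 255].

    Values at or below ``L - W/2`` clamp to 0, values above ``L + W/2`` clamp
    to 255, and the window interior is stretched linearly:
    ``Y = (X - L + W/2) * 255 / W``.  The result stays in floating point;
    quantization to uint8 (round-half-even) happens only on 8-bit export.
    """
    if img.value_kind != "ct_value":
        raise InvalidParameterError(
            f"window_transform expects a ct_value volume, got {img.value_kind!r}"
        )
    L, W = win.L, win.W
    x = img.voxels.astype(float)
    y = np.clip((x - L + W / 2.0) * 255.0 / W, 0.0, 255.0)
    # the clip already realizes the piecewise form: X <= L-W/2 -> 0, X > L+W/2 -> 255
    return img.with_voxels(y, value_kind="gray_float")


def equalize_histogram(img: ImageVolume, n_levels: int = 256) -> ImageVolume:
    """Cumulative-histogram equalization to ``n_levels`` gray levels.

    The mapping is monotone non-decreasing.  A constant image has a
    degenerate histogram and is returned unchanged (with a logged warning).
    """
    x = img.voxels.astype(float)
    if not np.isfinite(x).all():
        raise InvalidParameterError("equalize_histogram requires finite intensities")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        log.warning("equalize_histogram: constant image, returned unchanged")
        return img.with_voxels(x.copy(), value_kind="gray8" if img.value_kind == "gray8" else None)
    hist, edges = np.histogram(x, bins=n_levels, range=(lo, hi))
    cdf = hist.cumsum().astype(float)
    # standard normalization: smallest occupied bin maps to 0, last to n_levels-1
    cdf_min = cdf[cdf > 0][0]
    lut = np.round((cdf - cdf_min) / (cdf[-1] - cdf_min) * (n_levels - 1))
    lut = np.clip(lut, 0, n_levels - 1)
    bins = np.clip(((x - lo) / (hi - lo) * n_levels).astype(int), 0, n_levels - 1)
    return img.with_voxels(lut[bins], value_kind="gray8")


def trilinear_interpolate(corners, x, y, z):
    """Trilinear interpolation from 8 cube-corner values at fractions (x, y, z).

    ``corners`` is the sequence ``f000, f001, ..., f111`` where the subscript
    bits are ordered ``(z, y, x)``: ``f001`` is the x=1 corner and ``f100``
    the z=1 corner.  Fractions measure the distance from the 000 corner and
    must lie in [0, 1].  Corner values may be arrays (broadcast elementwise).
    """
    fx, fy, fz = (np.asarray(v, dtype=float) for v in (x, y, z))
    for name, f in (("x", fx), ("y", fy), ("z", fz)):
        if np.any(f < 0) or np.any(f > 1):
            raise OutOfRangeError(f"fraction {name} outside [0, 1]")
    c = [np.asarray(v, dtype=float) for v in corners]
    if len(c) != 8:
        raise InvalidParameterError(f"expected 8 corner values, got {len(c)}")
    out = 0.0
    for idx, val in enumerate(c):
        bz, by, bx = (idx >> 2) & 1, (idx >> 1) & 1, idx & 1
        w = (fx if bx else 1 - fx) * (fy if by else 1 - fy) * (fz if bz else 1 - fz)
        out = out + w * val
    return out


def interpolate_slices(img: ImageVolume, factor: int) -> ImageVolume:
    """Insert ``factor - 1`` equally spaced slices between consecutive slices.

    New slices are trilinear interpolations of their bracketing slices (for
    pure z-insertion the x/y fractions are zero, so the scheme is linear in
    z); original slices are preserved bit-exact.  The slice spacing becomes
    ``dz / factor`` and ``nz`` becomes ``(nz - 1) * factor + 1``.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 2:
        raise InvalidParameterError(f"factor must be an integer >= 2, got {factor}")
    nz = img.nz
    if nz < 2:
        raise InsufficientSlicesError("slice interpolation needs at least 2 slices")
    v = img.voxels
    out = np.empty(((nz - 1) * factor + 1,) + v.shape[1:], dtype=float)
    out[::factor] = v
    for j in range(1, factor):
        t = j / factor
        s0, s1 = v[:-1], v[1:]
        # z-only sampling: both bracketing slices supply all 4 in-plane corners
        out[j::factor] = trilinear_interpolate([s0, s0, s0, s0, s1, s1, s1, s1], 0.0, 0.0, t)
    dz, dy, dx = img.spacing
    return img.with_voxels(out, spacing=(dz / factor, dy, dx))


def median_filter_z(img: ImageVolume, window: int = 5) -> ImageVolume:
    """1-D median filter along the slice (z) axis with a clamped window.

    At the volume ends the window shrinks to the available slices rather
    than padding, so a single-slice volume passes through unchanged.
    """
    if window % 2 == 0 or window < 3:
        raise InvalidParameterError(f"median window must be odd and >= 3, got {window}")
    v = img.voxels
    half = window // 2
    out = np.empty_like(v, dtype=float)
    for k in range(v.shape[0]):
        lo, hi = max(0, k - half), min(v.shape[0], k + half + 1)
        out[k] = np.median(v[lo:hi], axis=0)
    return img.with_voxels(out)


def neighborhood_average(image2d, kernel: SmoothingKernel | None = None):
    """Weighted neighborhood averaging of a single 2-D slice.

    ``g(i,j) = sum_uv W_uv f(i+u, j+v) / sum_uv W_uv`` with reflect padding
    at the borders.  Linear; preserves constant images exactly.
    """
    kernel = kernel or SmoothingKernel.uniform(3)
    f = np.asarray(image2d, dtype=float)
    if f.ndim != 2:
        raise InvalidParameterError("neighborhood_average operates on a 2-D slice")
    w = kernel.weights / kernel.weights.sum()
    return ndimage.correlate(f, w, mode="reflect")


def denoise_stack(img: ImageVolume, kernel: SmoothingKernel | None = None) -> ImageVolume:
    """Two-step denoising for sequential images.

    First a 1-D median filter (window 5) along z exploits the correlation
    between neighboring slices; then each slice is smoothed in-plane by
    neighborhood averaging (3x3 uniform by default).  The order is fixed.
    """
    kernel = kernel or SmoothingKernel.uniform(3)
    step1 = median_filter_z(img, window=5)
    out = np.stack([neighborhood_average(s, kernel) for s in step1.voxels])
    return img.with_voxels(out)
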