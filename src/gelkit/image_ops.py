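"""Gel-image enhancement operations.

Brightness/contrast, grayscale conversion, colour inversion, rotation, flips,
outer cropping, inner cropping (excising a vertical strip of lanes) and lane
reordering.  Every operation is pure — it returns a new :class:`GelImage`
with one provenance entry appended — and geometric operations that permute
pixels (flips, 90-degree rotations, reorders) are lossless.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image import BANDS_BRIGHT, BANDS_DARK, GelImage

_GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


def adjust_intensity(img: GelImage, brightness: float = 0, contrast: float = 1.0,
                     invert: bool = False, grayscale: bool = False) -> GelImage:
    """Adjust pixel intensities.

    Applied in order: grayscale (ITU-R 601 luminance weights) -> contrast
    about mid-gray 128 and brightness offset -> inversion.  Per pixel,
    ``v' = clamp(round((v - 128) * contrast + 128 + brightness), 0, 255)``;
    inversion maps ``v' -> 255 - v'`` and flips the polarity flag.
    """
    if contrast <= 0:
        raise ValueError("contrast must be > 0")
    px = img.pixels.astype(float)
    if grayscale and px.ndim == 3:
        px = px @ _GRAY_WEIGHTS
    out = np.clip(np.rint((px - 128.0) * contrast + 128.0 + brightness), 0, 255)
    polarity = img.polarity
    if invert:
        out = 255.0 - out
        polarity = BANDS_DARK if polarity == BANDS_BRIGHT else BANDS_BRIGHT
    return img.derive(out.astype(np.uint8), "adjust_intensity", polarity=polarity,
                      brightness=brightness, contrast=contrast,
                      invert=invert, grayscale=grayscale)


def rotate(img: GelImage, angle_deg: float) -> GelImage:
    """Rotate by an arbitrary angle (counter-clockwise).

    Multiples of 90 degrees are exact pixel permutations; other angles use
    bilinear interpolation on an enlarged canvas filled with the median pixel
    value (an estimate of the gel background).
    """
    if angle_deg % 90 == 0:
        k = int(angle_deg // 90) % 4
        out = np.rot90(img.pixels, k=k)
    else:
        fill = float(np.median(img.pixels))
        out = ndimage.rotate(img.pixels.astype(float), angle_deg, reshape=True,
                             order=1, mode="constant", cval=fill,
                             axes=(1, 0) if img.pixels.ndim == 2 else (1, 0))
        out = np.clip(np.rint(out), 0, 255)
    return img.derive(np.ascontiguousarray(out).astype(np.uint8), "rotate",
                      angle_deg=angle_deg)


def flip(img: GelImage, axis: str) -> GelImage:
    """Mirror the image. `axis` is ``"horizontal"`` (left-right) or ``"vertical"``."""
    if axis not in ("horizontal", "vertical"):
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    out = img.pixels[:, ::-1] if axis == "horizontal" else img.pixels[::-1]
    return img.derive(np.ascontiguousarray(out), "flip", axis=axis)


def crop_outer(img: GelImage, x_lo: int, y_lo: int, x_hi: int, y_hi: int) -> GelImage:
    """Keep exactly the half-open rectangle ``[x_lo, x_hi) x [y_lo, y_hi)``."""
    if not (0 <= x_lo < x_hi <= img.width and 0 <= y_lo < y_hi <= img.height):
        raise ValueError("crop rectangle empty or outside image bounds")
    out = img.pixels[y_lo:y_hi, x_lo:x_hi]
    return img.derive(np.ascontiguousarray(out), "crop_outer",
                      x_lo=x_lo, y_lo=y_lo, x_hi=x_hi, y_hi=y_hi)


def transform_geometry(img: GelImage, op: str, **kwargs) -> GelImage:
    """Dispatch to :func:`rotate`, :func:`flip` or :func:`crop_outer` by name."""
    table = {"rotate": rotate, "flip": flip, "crop_outer": crop_outer}
    if op not in table:
        raise ValueError(f"unknown geometry op {op!r}; one of {sorted(table)}")
    return table[op](img, **kwargs)


def excise_strip(img: GelImage, x_lo: int, x_hi: int) -> GelImage:
    """Inner crop: remove columns ``[x_lo, x_hi)`` and stitch the remainder.

    Used to delete unwanted lanes from the middle of a gel; the new width is
    ``width - (x_hi - x_lo)``.
    """
    if not (0 <= x_lo < x_hi <= img.width):
        raise ValueError("strip must satisfy 0 <= x_lo < x_hi <= width")
    if x_hi - x_lo >= img.width:
        raise ValueError("cannot excise the full image width")
    out = np.concatenate([img.pixels[:, :x_lo], img.pixels[:, x_hi:]], axis=1)
    return img.derive(np.ascontiguousarray(out), "excise_strip", x_lo=x_lo, x_hi=x_hi)


def reorder_lanes(img: GelImage, lane_x_intervals, permutation) -> GelImage:
    """Cut lane strips and re-paste them in a new left-to-right order.

    `lane_x_intervals` are disjoint half-open column intervals sorted
    left-to-right; `permutation[k]` names the original lane index that should
    occupy the k-th strip position.  Columns outside the intervals (the
    gutters) stay exactly where they are; only strip contents move, so lane
    geometry is preserved when strips share a width.
    """
    ivs = [tuple(map(int, iv)) for iv in lane_x_intervals]
    for lo, hi in ivs:
        if not (0 <= lo < hi <= img.width):
            raise ValueError(f"interval [{lo}, {hi}) outside image")
    for (_, hi), (lo2, _) in zip(ivs, ivs[1:]):
        if lo2 < hi:
            raise ValueError("intervals must be disjoint and sorted left-to-right")
    perm = list(permutation)
    if sorted(perm) != list(range(len(ivs))):
        raise ValueError("permutation must be a bijection on lane indices")
    widths = [hi - lo for lo, hi in ivs]
    if [widths[i] for i in perm] != widths:
        raise ValueError("permuted strip widths do not fit the target slots")
    out = img.pixels.copy()
    for slot, src in enumerate(perm):
        lo, hi = ivs[slot]
        s_lo, s_hi = ivs[src]
        out[:, lo:hi] = img.pixels[:, s_lo:s_hi]
    return img.derive(out, "reorder_lanes", intervals=ivs, permutation=perm)
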