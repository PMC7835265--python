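"""Gel image container with provenance tracking.

A :class:`GelImage` wraps a ``uint8`` pixel grid (grayscale ``(H, W)`` or RGB
``(H, W, 3)``) together with a polarity flag saying whether bands are brighter
or darker than the background, and an append-only provenance log of the
operations applied so far.  All image operations in :mod:`gelkit.image_ops`
are pure: they return a new ``GelImage`` and leave the input untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

BANDS_BRIGHT = "bands-bright"
BANDS_DARK = "bands-dark"


@dataclass
class GelImage:
    """A gel photograph plus analysis metadata.

    Parameters
    ----------
    pixels : ndarray
        ``uint8`` array, shape ``(H, W)`` for grayscale or ``(H, W, 3)`` for RGB.
    polarity : str
        ``"bands-bright"`` (the internal canonical convention: signal is
        brighter than background) or ``"bands-dark"``.
    provenance : list of dict
        Ordered record of applied operations, one entry per operation.
    """

    pixels: np.ndarray
    polarity: str = BANDS_BRIGHT
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError("pixels must be (H, W) grayscale or (H, W, 3) RGB")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.polarity not in (BANDS_BRIGHT, BANDS_DARK):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_grayscale(self) -> bool:
        return self.pixels.ndim == 2

    def derive(self, pixels: np.ndarray, op: str, polarity: str | None = None,
               **params) -> "GelImage":
        """Return a new image with `op(params)` appended to the provenance."""
        entry = {"op": op, **params}
        return GelImage(
            pixels=pixels,
            polarity=self.polarity if polarity is None else polarity,
            provenance=[*self.provenance, entry],
        )


def load_image(path, polarity: str = BANDS_BRIGHT) -> GelImage:
    """Read a PNG/TIFF/JPEG gel photograph as a :class:`GelImage`."""
    with Image.open(path) as im:
        if im.mode in ("L", "I;16", "I"):
            arr = np.asarray(im.convert("L"))
        elif im.mode in ("RGB", "RGBA", "P", "LA"):
            arr = np.asarray(im.convert("RGB"))
        else:
            arr = np.asarray(im.convert("RGB"))
    return GelImage(pixels=arr.astype(np.uint8), polarity=polarity,
                    provenance=[{"op": "load", "path": str(path)}])


def save_image(img: GelImage, path) -> None:
    """Write the pixel grid as an 8-bit PNG (grayscale or RGB)."""
    Image.fromarray(img.pixels).save(path, format="PNG")
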