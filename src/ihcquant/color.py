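"""Pixel-level RGB color-box segmentation and sentinel masking.

These primitives realise the color model of the quantification procedure:
a stain class (DAB brown at a given intensity, hematoxylin blue) is defined
by an axis-aligned box in RGB space with inclusive per-channel bounds, and
objects already accounted for are removed from later segmentation passes by
recoloring their pixels with a sentinel color that lies outside every
positive range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ColorRange",
    "as_rgb_image",
    "segment_by_color",
    "apply_sentinel_mask",
    "mask_union",
    "mask_area",
]


@dataclass(frozen=True)
class ColorRange:
    """Inclusive per-channel RGB bounds defining one stain class.

    A pixel belongs to the range iff ``r_lo <= R <= r_hi`` and likewise for
    G and B. Bounds are inclusive on both ends, matching the range semantics
    of interactive color-segmentation tools.
    """

    r_lo: int
    r_hi: int
    g_lo: int
    g_hi: int
    b_lo: int
    b_hi: int

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            lo = getattr(self, f"{name}_lo")
            hi = getattr(self, f"{name}_hi")
            if not (0 <= lo <= 255 and 0 <= hi <= 255):
                raise ValueError(
                    f"ColorRange {name}-channel bounds must lie in [0, 255], "
                    f"got [{lo}, {hi}]"
                )
            if lo > hi:
                raise ValueError(
                    f"ColorRange {name}-channel has lo > hi ({lo} > {hi})"
                )

    @property
    def lo(self) -> np.ndarray:
        return np.array([self.r_lo, self.g_lo, self.b_lo], dtype=np.int16)

    @property
    def hi(self) -> np.ndarray:
        return np.array([self.r_hi, self.g_hi, self.b_hi], dtype=np.int16)

    def contains(self, rgb: Sequence[int]) -> bool:
        """True iff the single color triplet lies inside the box."""
        r, g, b = (int(v) for v in rgb)
        return (
            self.r_lo <= r <= self.r_hi
            and self.g_lo <= g <= self.g_hi
            and self.b_lo <= b <= self.b_hi
        )

    @staticmethod
    def hull(ranges: Iterable["ColorRange"]) -> "ColorRange":
        """Smallest box containing every given range (per-channel hull)."""
        ranges = list(ranges)
        if not ranges:
            raise ValueError("hull of an empty collection of ranges")
        lo = np.min([r.lo for r in ranges], axis=0)
        hi = np.max([r.hi for r in ranges], axis=0)
        return ColorRange(
            int(lo[0]), int(hi[0]), int(lo[1]), int(hi[1]), int(lo[2]), int(hi[2])
        )


def as_rgb_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and return an H x W x 3 uint8 RGB image array.

    Raises ``ValueError`` for wrong shape/dtype or a zero-pixel image.
    """
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image has zero pixels")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ValueError(
                f"expected 8-bit channel values in [0, 255], got dtype {arr.dtype}"
            )
    return arr


def segment_by_color(image: np.ndarray, crange: ColorRange) -> np.ndarray:
    """Boolean mask, true exactly where all three channels fall inside
    the inclusive bounds of ``crange``."""
    img = as_rgb_image(image)
    px = img.astype(np.int16, copy=False)
    lo, hi = crange.lo, crange.hi
    return np.logical_and(px >= lo, px <= hi).all(axis=2)


def apply_sentinel_mask(
    image: np.ndarray, mask: np.ndarray, sentinel: Sequence[int]
) -> np.ndarray:
    """Return a copy of ``image`` with masked pixels recolored to ``sentinel``.

    The input image is left unmodified. Used to displace already-selected or
    negative objects outside the segmentation range of later passes.
    """
    img = as_rgb_image(image)
    m = np.asarray(mask, dtype=bool)
    if m.shape != img.shape[:2]:
        raise ValueError(
            f"mask shape {m.shape} does not match image shape {img.shape[:2]}"
        )
    s = np.asarray(sentinel, dtype=np.uint8)
    if s.shape != (3,):
        raise ValueError("sentinel must be an (R, G, B) triplet")
    out = img.copy()
    out[m] = s
    return out


def mask_union(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Pixelwise OR of one or more same-shaped boolean masks."""
    if len(masks) == 0:
        raise ValueError("mask_union of an empty list")
    out = np.asarray(masks[0], dtype=bool).copy()
    for m in masks[1:]:
        m = np.asarray(m, dtype=bool)
        if m.shape != out.shape:
            raise ValueError(f"mask shapes differ: {m.shape} vs {out.shape}")
        np.logical_or(out, m, out=out)
    return out


def mask_area(mask: np.ndarray) -> int:
    """Number of true pixels (px^2)."""
    return int(np.count_nonzero(np.asarray(mask, dtype=bool)))
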