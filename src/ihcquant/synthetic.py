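"""Synthetic IHC brightfield scene generator with ground truth.

Emulates what the segmentation procedure actually consumes: DAB-brown
positive nuclei spanning a darkest, a mid and a light intensity band,
hematoxylin-blue negative nuclei, and — at a controllable level — diffuse
light-brown spurious background deposits. Nuclei are flat-shaded ellipses
with per-pixel color jitter kept strictly inside the class color box, so
palette containment is a hard contract rather than a statistical tendency.
Background deposits are amorphous Gaussian-smoothed blobs whose pixel
colors straddle the light positive band and its lighter extension: faint
(low-level) deposits sit almost entirely inside the light positive range,
heavy (high-level) deposits extend into the washed-out hues beyond it.

Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .color import ColorRange
from .config import RunConfig, default_config

__all__ = [
    "NucleusClass",
    "Nucleus",
    "SyntheticScene",
    "generate_scene",
    "scene_ground_truth",
    "BACKGROUND_COVERAGE",
    "BACKGROUND_EXTENSION_FRACTION",
]

#: Approximate canvas fraction covered by spurious-stain deposits per level.
BACKGROUND_COVERAGE = {"none": 0.0, "low": 0.03, "high": 0.12}
#: Fraction of deposit pixels drawn from the lighter extension zone
#: (inside bg2 but outside the positive hull) per level.
BACKGROUND_EXTENSION_FRACTION = {"none": 0.0, "low": 0.08, "high": 0.5}

_TISSUE_BASE = (244, 242, 239)
_JITTER = 6  # per-pixel color jitter amplitude, px kept inside the class box
_CLASS_SPLIT = (0.4, 0.4, 0.2)  # dark / mid / light share of positives


class NucleusClass(enum.Enum):
    POS_DARK = 1
    POS_MID = 2
    POS_LIGHT = 3
    NEG = 4


@dataclass(frozen=True)
class Nucleus:
    center: Tuple[float, float]  # (row, col) px
    axes: Tuple[float, float]  # semi-axes (a, b) px
    orientation: float  # radians
    nucleus_class: NucleusClass


@dataclass
class SyntheticScene:
    image: np.ndarray
    nuclei: List[Nucleus]
    background_level: str
    background_pixels: np.ndarray  # visible (non-nucleus) deposit pixels
    seed: int
    class_map: np.ndarray  # uint8, 0 = no nucleus, else NucleusClass value

    @property
    def n_positive(self) -> int:
        return sum(1 for n in self.nuclei if n.nucleus_class is not NucleusClass.NEG)


def scene_ground_truth(scene: SyntheticScene) -> int:
    """Ground-truth number of positive nuclei (the synthetic gold standard)."""
    return scene.n_positive


def _class_range(cfg: RunConfig, cls: NucleusClass) -> ColorRange:
    return cfg.ranges[
        {
            NucleusClass.POS_DARK: "darkest",
            NucleusClass.POS_MID: "mid",
            NucleusClass.POS_LIGHT: "light",
            NucleusClass.NEG: "negative",
        }[cls]
    ]


def _sample_base_color(rng: np.random.Generator, crange: ColorRange) -> np.ndarray:
    """Base color such that +-_JITTER stays inside the box on every channel."""
    lo = crange.lo + _JITTER
    hi = crange.hi - _JITTER
    if np.any(lo > hi):
        raise ValueError("color range too narrow for the jitter margin")
    return rng.integers(lo, hi + 1)


def _draw_ellipse(
    image: np.ndarray,
    class_map: np.ndarray,
    rng: np.random.Generator,
    nucleus: Nucleus,
    crange: ColorRange,
) -> None:
    h, w = class_map.shape
    cy, cx = nucleus.center
    a, b = nucleus.axes
    theta = nucleus.orientation
    rmax = max(a, b)
    r0, r1 = max(0, int(cy - rmax) - 1), min(h, int(cy + rmax) + 2)
    c0, c1 = max(0, int(cx - rmax) - 1), min(w, int(cx + rmax) + 2)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy, dx = rr - cy, cc - cx
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    n_px = int(inside.sum())
    if n_px == 0:
        return
    base = _sample_base_color(rng, crange)
    jitter = rng.integers(-_JITTER, _JITTER + 1, size=(n_px, 3))
    sub = image[r0:r1, c0:c1]
    sub[inside] = (base + jitter).astype(np.uint8)
    class_map[r0:r1, c0:c1][inside] = nucleus.nucleus_class.value


def _too_close(
    center: np.ndarray,
    radius: float,
    centers: np.ndarray,
    radii: np.ndarray,
    skip: Optional[slice] = None,
) -> bool:
    if centers.shape[0] == 0:
        return False
    keep = np.ones(centers.shape[0], dtype=bool)
    if skip is not None:
        keep[skip] = False
    if not keep.any():
        return False
    d = np.hypot(*(centers[keep] - center).T)
    return bool(np.any(d <= radii[keep] + radius + 3.0))


def _place_nuclei(
    rng: np.random.Generator,
    n_positive: int,
    n_negative: int,
    overlap_fraction: float,
    height: int,
    width: int,
) -> List[Tuple[np.ndarray, Tuple[float, float], float, bool]]:
    """Sample centers, semi-axes and orientations with rejection sampling.

    Returns (center, (a, b), orientation, is_positive) in draw order.
    Isolated nuclei keep a >= 3 px rim from every other nucleus;
    ``overlap_fraction`` of the positives are laid out as chains of 2-4
    touching ellipses. Raises ``RuntimeError`` on infeasible packing.
    """

    def _geometry() -> Tuple[float, float, float]:
        r = rng.uniform(10.5, 13.5)
        s = rng.uniform(1.0, 1.25)
        return r * math.sqrt(s), r / math.sqrt(s), rng.uniform(0.0, math.pi)

    margin = 18.0
    centers = np.empty((0, 2))
    radii = np.empty((0,))
    placed: List[Tuple[np.ndarray, Tuple[float, float], float, bool]] = []

    def _commit(center, a, b, theta, positive) -> None:
        nonlocal centers, radii
        centers = np.vstack([centers, center[None]])
        radii = np.append(radii, max(a, b))
        placed.append((center, (a, b), theta, positive))

    def _place_isolated(positive: bool) -> None:
        a, b, theta = _geometry()
        for _ in range(300):
            center = np.array(
                [rng.uniform(margin, height - margin),
                 rng.uniform(margin, width - margin)]
            )
            if not _too_close(center, max(a, b), centers, radii):
                _commit(center, a, b, theta, positive)
                return
        raise RuntimeError(
            f"infeasible packing: cannot place nucleus "
            f"({len(placed)} placed in {height}x{width})"
        )

    n_clustered = int(round(overlap_fraction * n_positive))
    n_isolated_pos = n_positive - n_clustered
    remaining = n_clustered
    while remaining >= 2:
        k = int(min(rng.integers(2, 5), remaining))
        for _attempt in range(40):
            chain: List[Tuple[np.ndarray, float, float, float]] = []
            start_idx = centers.shape[0]
            ok = True
            for i in range(k):
                a, b, theta = _geometry()
                placed_member = False
                for _ in range(60):
                    if i == 0:
                        center = np.array(
                            [rng.uniform(margin, height - margin),
                             rng.uniform(margin, width - margin)]
                        )
                    else:
                        prev_c, prev_a, _, _ = chain[-1]
                        phi = rng.uniform(0.0, 2.0 * math.pi)
                        dist = 0.88 * (prev_a + max(a, b))
                        center = prev_c + dist * np.array(
                            [math.sin(phi), math.cos(phi)]
                        )
                        if not (
                            margin <= center[0] <= height - margin
                            and margin <= center[1] <= width - margin
                        ):
                            continue
                    # non-adjacent chain members may touch but not engulf
                    overlap_bad = any(
                        np.hypot(*(c - center)) <= 0.95 * (r + max(a, b))
                        for c, r, _t, _s in chain[:-1]
                    )
                    if not overlap_bad and not _too_close(
                        center, max(a, b), centers, radii,
                        skip=slice(start_idx, None),
                    ):
                        chain.append((center, max(a, b), theta, a / max(a, b)))
                        _commit(center, a, b, theta, True)
                        placed_member = True
                        break
                if not placed_member:
                    ok = False
                    # roll back this chain and retry it from scratch
                    n_drop = len(chain)
                    if n_drop:
                        centers = centers[:start_idx]
                        radii = radii[:start_idx]
                        del placed[start_idx:]
                    break
            if ok:
                break
        else:
            raise RuntimeError("infeasible packing: cannot place nucleus chain")
        remaining -= k
    if remaining == 1:
        n_isolated_pos += 1
    for _ in range(n_isolated_pos):
        _place_isolated(True)
    for _ in range(n_negative):
        _place_isolated(False)
    return placed


def _sample_extension_colors(
    rng: np.random.Generator, n: int, bg2: ColorRange, light: ColorRange
) -> np.ndarray:
    """Uniform colors in the bg2 box outside the light positive box."""
    out = np.empty((n, 3), dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.integers(bg2.lo, bg2.hi + 1, size=(2 * (n - filled) + 8, 3))
        in_light = np.logical_and(draw >= light.lo, draw <= light.hi).all(axis=1)
        good = draw[~in_light]
        take = min(good.shape[0], n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def _background_mask(
    rng: np.random.Generator,
    level: str,
    height: int,
    width: int,
) -> np.ndarray:
    """Amorphous deposit support: unions of jittered discs, smoothed and
    re-thresholded, placed uniformly over the tissue."""
    target = BACKGROUND_COVERAGE[level] * height * width
    if target <= 0:
        return np.zeros((height, width), dtype=bool)
    blob_lo, blob_hi = (8000, 12000) if level == "low" else (14000, 20000)
    raw = np.zeros((height, width), dtype=bool)
    rr, cc = np.mgrid[0:height, 0:width]
    guard = 0
    while raw.sum() < target and guard < 64:
        guard += 1
        area = rng.uniform(blob_lo, blob_hi)
        disc_r = max(10.0, math.sqrt(area) / 6.0)
        y = float(rng.uniform(60, height - 60))
        x = float(rng.uniform(60, width - 60))
        blob = np.zeros_like(raw)
        # random walk of overlapping discs: consecutive steps shorter than
        # the diameter keep every blob one connected region
        for _ in range(400):
            r0, r1 = max(0, int(y - disc_r) - 1), min(height, int(y + disc_r) + 2)
            c0, c1 = max(0, int(x - disc_r) - 1), min(width, int(x + disc_r) + 2)
            if r0 < r1 and c0 < c1:
                sub = (rr[r0:r1, c0:c1] - y) ** 2 + (cc[r0:r1, c0:c1] - x) ** 2
                blob[r0:r1, c0:c1] |= sub <= disc_r**2
            if blob.sum() >= area:
                break
            step = disc_r * rng.uniform(0.6, 1.2)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            y = float(np.clip(y + step * math.sin(phi), 40, height - 40))
            x = float(np.clip(x + step * math.cos(phi), 40, width - 40))
        raw |= blob
    smooth = ndimage.gaussian_filter(raw.astype(float), sigma=3.0)
    return smooth > 0.5


def generate_scene(
    n_positive: int,
    n_negative: int = 0,
    background_level: str = "none",
    overlap_fraction: float = 0.2,
    width: int = 696,
    height: int = 520,
    seed: int = 0,
    cfg: Optional[RunConfig] = None,
) -> SyntheticScene:
    """Generate one IHC-like scene with per-nucleus ground truth.

    Parameters mirror the conditions the pipeline is validated under:
    counts of positive/negative nuclei, the spurious-background level
    (none/low/high), the fraction of positives laid out as touching
    clusters, the canvas size (default half the nominal capture size for
    speed) and the seed.
    """
    if background_level not in BACKGROUND_COVERAGE:
        raise ValueError(
            f"background_level must be one of {sorted(BACKGROUND_COVERAGE)}"
        )
    if n_positive < 0 or n_negative < 0:
        raise ValueError("nucleus counts must be >= 0")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if width < 64 or height < 64:
        raise ValueError("canvas must be at least 64 x 64 px")
    cfg = cfg or default_config()
    rng = np.random.default_rng(seed)

    placed = _place_nuclei(
        rng, n_positive, n_negative, overlap_fraction, height, width
    )
    pos_classes = rng.choice(
        [NucleusClass.POS_DARK, NucleusClass.POS_MID, NucleusClass.POS_LIGHT],
        size=max(1, n_positive),
        p=_CLASS_SPLIT,
    )
    nuclei: List[Nucleus] = []
    ipos = 0
    for center, axes, theta, positive in placed:
        cls = pos_classes[ipos] if positive else NucleusClass.NEG
        if positive:
            ipos += 1
        nuclei.append(
            Nucleus(
                center=(float(center[0]), float(center[1])),
                axes=axes,
                orientation=theta,
                nucleus_class=cls,
            )
        )

    # tissue base with mild per-pixel jitter (stays well clear of bg2)
    image = np.clip(
        np.array(_TISSUE_BASE, dtype=np.int16)
        + rng.integers(-_JITTER, _JITTER + 1, size=(height, width, 3)),
        0,
        255,
    ).astype(np.uint8)

    blob_mask = _background_mask(rng, background_level, height, width)
    if blob_mask.any():
        n_bg = int(blob_mask.sum())
        f_ext = BACKGROUND_EXTENSION_FRACTION[background_level]
        ext_flag = rng.random(n_bg) < f_ext
        colors = np.empty((n_bg, 3), dtype=np.int64)
        light = cfg.ranges["light"]
        n_in = int((~ext_flag).sum())
        if n_in:
            colors[~ext_flag] = rng.integers(light.lo, light.hi + 1, size=(n_in, 3))
        n_ext = int(ext_flag.sum())
        if n_ext:
            colors[ext_flag] = _sample_extension_colors(
                rng, n_ext, cfg.ranges["bg2"], light
            )
        image[blob_mask] = colors.astype(np.uint8)

    class_map = np.zeros((height, width), dtype=np.uint8)
    for nucleus in nuclei:
        _draw_ellipse(image, class_map, rng, nucleus, _class_range(cfg, nucleus.nucleus_class))

    background_pixels = blob_mask & (class_map == 0)
    return SyntheticScene(
        image=image,
        nuclei=nuclei,
        background_level=background_level,
        background_pixels=background_pixels,
        seed=seed,
        class_map=class_map,
    )
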