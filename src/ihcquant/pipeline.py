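"""The multistep segmentation procedure with background discrimination.

Three color passes build disjoint object maps of positive (DAB-brown)
nuclei, darkest first. A discriminative step then segments the *non-selected*
brown with two ranges: the primary positive hull (area 1) and a lighter
extension band (area 2). If area 2 is empty the image has no spurious
background and the legacy wide-range macro is applied; otherwise the ratio
area2/area1 routes the image to a restrictive macro (the three passes as
they stand) for low background, or to the full macro for high background,
whose final light pass keeps only the clearest nucleus-like objects under
the strictest morphological band.

Negative (hematoxylin-blue) nuclei, and pixels already selected by earlier
passes, are displaced out of every positive color range by sentinel
recoloring before each pass, so the maps are pairwise disjoint by
construction.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .color import (
    apply_sentinel_mask,
    as_rgb_image,
    mask_area,
    mask_union,
    segment_by_color,
)
from .config import RunConfig
from .objects import MorphFilter, ObjectMap, StepTag, filter_objects, label_objects

__all__ = [
    "BackgroundClass",
    "MacroName",
    "BackgroundAssessment",
    "MacroResult",
    "build_map1",
    "build_maps23",
    "assess_background",
    "run_none_bg_macro",
    "run_restrictive_macro",
    "run_full_macro",
    "analyze_image",
]

logger = logging.getLogger(__name__)


class BackgroundClass(enum.Enum):
    NONE = "NONE"
    LOW = "LOW"
    HIGH = "HIGH"


class MacroName(enum.Enum):
    NONE_BG = "NONE_BG"
    RESTRICTIVE = "RESTRICTIVE"
    FULL = "FULL"


@dataclass(frozen=True)
class BackgroundAssessment:
    """Spurious-stain measurement driving macro routing.

    ``area1`` is the pixel support of the primary brown range outside the
    selected positives; ``area2`` the support of the lighter extension range
    outside both. ``area2 == 0`` means no background (class NONE); otherwise
    the ratio area2/area1 is compared against the configured threshold
    (ratio >= threshold, or area1 == 0, classifies as HIGH).
    """

    area1: int
    area2: int
    ratio: Optional[float]
    background_class: BackgroundClass


@dataclass
class MacroResult:
    macro_used: MacroName
    selected: ObjectMap
    assessment: BackgroundAssessment
    per_step_maps: Dict[StepTag, ObjectMap]


def _segment_with_sentinel(
    image: np.ndarray,
    masked: np.ndarray,
    crange,
    cfg: RunConfig,
) -> np.ndarray:
    """Sentinel-recolor ``masked`` pixels, then segment with ``crange``."""
    work = apply_sentinel_mask(image, masked, cfg.sentinel_color)
    return segment_by_color(work, crange)


def _labeled(
    image: np.ndarray,
    mask: np.ndarray,
    tag: StepTag,
    mfilter: MorphFilter,
    cfg: RunConfig,
) -> ObjectMap:
    omap = label_objects(
        mask, image, step_tag=tag,
        fill_holes=cfg.fill_holes, exclude_border=cfg.exclude_border,
    )
    return filter_objects(omap, mfilter)


def build_map1(image: np.ndarray, cfg: RunConfig) -> ObjectMap:
    """First pass: mask negatives and light positives, select the darkest
    brown objects."""
    img = as_rgb_image(image)
    blockout = mask_union([
        segment_by_color(img, cfg.ranges["negative"]),
        segment_by_color(img, cfg.ranges["light"]),
    ])
    mask = _segment_with_sentinel(img, blockout, cfg.ranges["darkest"], cfg)
    return _labeled(img, mask, StepTag.MAP1, cfg.morph_filters["map1"], cfg)


def build_maps23(
    image: np.ndarray, map1: ObjectMap, cfg: RunConfig
) -> Tuple[ObjectMap, ObjectMap]:
    """Second and third passes: mask negatives plus already-selected pixels,
    select the clearer positives with the mid then the light brown range.
    The returned maps are pixel-disjoint with each other and with map 1."""
    img = as_rgb_image(image)
    negative = segment_by_color(img, cfg.ranges["negative"])
    blocked2 = mask_union([negative, map1.mask])
    m2 = _segment_with_sentinel(img, blocked2, cfg.ranges["mid"], cfg)
    map2 = _labeled(img, m2, StepTag.MAP2, cfg.morph_filters["map2"], cfg)
    blocked3 = mask_union([negative, map1.mask, map2.mask])
    m3 = _segment_with_sentinel(img, blocked3, cfg.ranges["light"], cfg)
    map3 = _labeled(img, m3, StepTag.MAP3, cfg.morph_filters["map3"], cfg)
    return map2, map3


def assess_background(
    image: np.ndarray, selected: np.ndarray, cfg: RunConfig
) -> BackgroundAssessment:
    """Discriminative step: measure non-selected brown with two ranges.

    area1 = |bg1 \\ selected|, area2 = |bg2 \\ (selected ∪ bg1)| — the two
    supports are disjoint, so area2 counts only diffuse stain lighter than
    the primary positive hull. Class NONE iff area2 == 0; otherwise LOW when
    area2/area1 < ratio_threshold, HIGH when the ratio reaches the threshold
    or when area1 == 0.
    """
    img = as_rgb_image(image)
    sel = np.asarray(selected, dtype=bool)
    bg1 = segment_by_color(img, cfg.ranges["bg1"])
    bg2 = segment_by_color(img, cfg.ranges["bg2"])
    area1 = mask_area(bg1 & ~sel)
    area2 = mask_area(bg2 & ~sel & ~bg1)
    if area2 == 0:
        return BackgroundAssessment(area1, 0, None, BackgroundClass.NONE)
    if area1 == 0:
        return BackgroundAssessment(area1, area2, None, BackgroundClass.HIGH)
    ratio = area2 / area1
    cls = (
        BackgroundClass.LOW if ratio < cfg.ratio_threshold else BackgroundClass.HIGH
    )
    return BackgroundAssessment(area1, area2, ratio, cls)


def run_none_bg_macro(
    image: np.ndarray,
    cfg: RunConfig,
    assessment: Optional[BackgroundAssessment] = None,
) -> MacroResult:
    """Legacy wide-range macro for images without background: mask negatives,
    segment darkest-to-lightest brown in one pass, gate with the permissive
    wide-step filter (clusters of any size are kept for area splitting)."""
    img = as_rgb_image(image)
    negative = segment_by_color(img, cfg.ranges["negative"])
    mask = _segment_with_sentinel(img, negative, cfg.ranges["wide_positive"], cfg)
    wide = _labeled(img, mask, StepTag.WIDE, cfg.morph_filters["wide"], cfg)
    if assessment is None:
        assessment = assess_background(img, wide.mask, cfg)
    return MacroResult(
        macro_used=MacroName.NONE_BG,
        selected=wide,
        assessment=assessment,
        per_step_maps={StepTag.WIDE: wide},
    )


def _relabel_union(
    image: np.ndarray, maps: Dict[StepTag, ObjectMap], cfg: RunConfig
) -> ObjectMap:
    union = mask_union([m.mask for m in maps.values()])
    return label_objects(
        union, image, step_tag=StepTag.FINAL,
        fill_holes=False, exclude_border=False,
    )


def run_restrictive_macro(
    image: np.ndarray,
    cfg: RunConfig,
    prior: Optional[Tuple[ObjectMap, ObjectMap, ObjectMap]] = None,
    assessment: Optional[BackgroundAssessment] = None,
) -> MacroResult:
    """Low-background macro: the three passes as they stand; the selection
    is the union of maps 1-3."""
    img = as_rgb_image(image)
    if prior is None:
        m1 = build_map1(img, cfg)
        m2, m3 = build_maps23(img, m1, cfg)
    else:
        m1, m2, m3 = prior
    maps = {StepTag.MAP1: m1, StepTag.MAP2: m2, StepTag.MAP3: m3}
    selected = _relabel_union(img, maps, cfg)
    if assessment is None:
        assessment = assess_background(img, selected.mask, cfg)
    return MacroResult(MacroName.RESTRICTIVE, selected, assessment, maps)


def run_full_macro(
    image: np.ndarray,
    cfg: RunConfig,
    prior: Optional[Tuple[ObjectMap, ObjectMap]] = None,
    assessment: Optional[BackgroundAssessment] = None,
    final_enabled: bool = True,
) -> MacroResult:
    """High-background macro: darkest and mid passes, supplemented by a
    final light pass that keeps only the clearest nucleus-like objects.

    The final step is the light color pass gated with the strict FINAL
    morphological band (small area, near-circular), which rejects the
    diffuse light-brown background fragments the permissive third pass
    would admit. ``final_enabled=False`` drops the light pass entirely
    (selection shrinks monotonically).
    """
    img = as_rgb_image(image)
    if prior is None:
        m1 = build_map1(img, cfg)
        negative = segment_by_color(img, cfg.ranges["negative"])
        m2mask = _segment_with_sentinel(
            img, mask_union([negative, m1.mask]), cfg.ranges["mid"], cfg
        )
        m2 = _labeled(img, m2mask, StepTag.MAP2, cfg.morph_filters["map2"], cfg)
    else:
        m1, m2 = prior
    maps: Dict[StepTag, ObjectMap] = {StepTag.MAP1: m1, StepTag.MAP2: m2}
    if final_enabled:
        negative = segment_by_color(img, cfg.ranges["negative"])
        blocked = mask_union([negative, m1.mask, m2.mask])
        fmask = _segment_with_sentinel(img, blocked, cfg.ranges["light"], cfg)
        fmap = _labeled(img, fmask, StepTag.FINAL, cfg.morph_filters["final"], cfg)
        maps[StepTag.FINAL] = fmap
    selected = _relabel_union(img, maps, cfg)
    if assessment is None:
        assessment = assess_background(img, selected.mask, cfg)
    return MacroResult(MacroName.FULL, selected, assessment, maps)


def analyze_image(image: np.ndarray, cfg: RunConfig) -> MacroResult:
    """Run the full automated procedure on one image.

    Builds maps 1-3, assesses the background on their union, and dispatches
    exactly one macro: NONE -> legacy wide-range macro (maps 1-3 discarded),
    LOW -> restrictive macro, HIGH -> full macro with the strict final pass.
    Deterministic: a pure function of (image, config).
    """
    img = as_rgb_image(image)
    m1 = build_map1(img, cfg)
    m2, m3 = build_maps23(img, m1, cfg)
    selected = mask_union([m1.mask, m2.mask, m3.mask])
    assessment = assess_background(img, selected, cfg)
    cls = assessment.background_class
    if cls is BackgroundClass.NONE:
        result = run_none_bg_macro(img, cfg, assessment=assessment)
    elif cls is BackgroundClass.LOW:
        result = run_restrictive_macro(
            img, cfg, prior=(m1, m2, m3), assessment=assessment
        )
    else:
        result = run_full_macro(img, cfg, prior=(m1, m2), assessment=assessment)
    logger.info(
        "background_class=%s area1=%d area2=%d ratio=%s macro_used=%s n_objects=%d",
        cls.value,
        assessment.area1,
        assessment.area2,
        "NA" if assessment.ratio is None else f"{assessment.ratio:.4f}",
        result.macro_used.value,
        result.selected.n_objects,
    )
    return result
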