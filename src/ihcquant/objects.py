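"""Connected-component labeling, per-object morphometry and shape gating.

Candidate nuclei are 8-connected components of a color-segmentation mask.
Each object carries area, perimeter, roundness, centroid and mean color;
the segmentation macros then gate objects on area and roundness bands.

Perimeter is the weighted contour-step length of the outer boundary walk:
the closed Moore-neighbor trace of the component, with isothetic steps
counting 1 and diagonal steps sqrt(2). Holes do not contribute. Roundness
is perimeter^2 / (4 pi area), 1 for a perfect circle, clamped below at 1
against digitization undershoot; a single-pixel object is 1 by convention.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .color import as_rgb_image

__all__ = [
    "StepTag",
    "ObjectFeatures",
    "ObjectMap",
    "MorphFilter",
    "label_objects",
    "compute_roundness",
    "trace_perimeter",
    "filter_objects",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)

# Clockwise Moore neighborhood starting at north, with step lengths.
_OFFS = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_IDX = {off: i for i, off in enumerate(_OFFS)}
_SQRT2 = math.sqrt(2.0)


class StepTag(enum.Enum):
    """Which pass of the procedure produced an object map."""

    MAP1 = "MAP1"
    MAP2 = "MAP2"
    MAP3 = "MAP3"
    FINAL = "FINAL"
    WIDE = "WIDE"


@dataclass(frozen=True)
class ObjectFeatures:
    label: int
    area: int
    perimeter: float
    roundness: float
    centroid: Tuple[float, float]  # (row, col), px
    mean_color: Tuple[float, float, float]


@dataclass
class ObjectMap:
    """A labeled set of segmented objects from one pipeline pass.

    ``labels`` is 0 on background and ``objects[k].label == k + 1``; the
    union of object pixels equals the true set of ``mask``.
    """

    mask: np.ndarray
    labels: np.ndarray
    objects: List[ObjectFeatures]
    step_tag: StepTag = StepTag.WIDE

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def total_area(self) -> int:
        return int(sum(o.area for o in self.objects))


@dataclass(frozen=True)
class MorphFilter:
    """Closed area and roundness bands an object must satisfy to be kept."""

    area_min: float = 1.0
    area_max: float = math.inf
    roundness_min: float = 1.0
    roundness_max: float = math.inf

    def __post_init__(self) -> None:
        if self.area_min < 1 or self.area_min > self.area_max:
            raise ValueError(
                f"invalid area band [{self.area_min}, {self.area_max}]"
            )
        if self.roundness_min < 1 or self.roundness_min > self.roundness_max:
            raise ValueError(
                f"invalid roundness band [{self.roundness_min}, {self.roundness_max}]"
            )

    def accepts(self, obj: ObjectFeatures) -> bool:
        return (
            self.area_min <= obj.area <= self.area_max
            and self.roundness_min <= obj.roundness <= self.roundness_max
        )


def trace_perimeter(mask: np.ndarray) -> float:
    """Contour-step length of the outer boundary of one 8-connected object.

    The closed Moore-neighbor boundary walk is followed from the raster-first
    pixel; each orthogonal step adds 1 and each diagonal step sqrt(2). A
    single pixel has no walk and returns 0. One-pixel-wide protrusions are
    traversed on both sides, as a contour follower does.
    """
    m = np.asarray(mask, dtype=bool)
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty pixel set")
    if n == 1:
        return 0.0
    # pad so neighbor lookups never leave the array
    p = np.pad(m, 1)
    rows, cols = np.nonzero(p)
    start = (int(rows[0]), int(cols[0]))
    prev = (start[0], start[1] - 1)  # virtual backtrack west of the start
    cur = start
    first_move: Optional[Tuple[Tuple[int, int], Tuple[int, int]]] = None
    perim = 0.0
    max_iter = 4 * n + 8
    for _ in range(max_iter):
        i = _IDX[(prev[0] - cur[0], prev[1] - cur[1])]
        nxt = None
        backtrack = prev
        for k in range(1, 9):
            j = (i + k) % 8
            cand = (cur[0] + _OFFS[j][0], cur[1] + _OFFS[j][1])
            if p[cand]:
                nxt = cand
                break
            backtrack = cand
        assert nxt is not None  # n >= 2 and object 8-connected
        if first_move is None:
            first_move = (cur, nxt)
        elif (cur, nxt) == first_move:
            break
        perim += 1.0 if (nxt[0] == cur[0] or nxt[1] == cur[1]) else _SQRT2
        prev = backtrack
        cur = nxt
    return perim


def compute_roundness(mask: np.ndarray) -> float:
    """Roundness perimeter^2 / (4 pi area) of one object's pixel set,
    clamped below at 1; a single pixel returns 1 by convention."""
    m = np.asarray(mask, dtype=bool)
    area = int(m.sum())
    if area == 0:
        raise ValueError("empty pixel set")
    if area == 1:
        return 1.0
    perim = trace_perimeter(m)
    return max(1.0, perim * perim / (4.0 * math.pi * area))


def _features_for(
    labels: np.ndarray, image: np.ndarray, n_labels: int
) -> List[ObjectFeatures]:
    flat = labels.ravel()
    areas = np.bincount(flat, minlength=n_labels + 1)[1:]
    rows, cols = np.indices(labels.shape)
    r_sum = np.bincount(flat, weights=rows.ravel(), minlength=n_labels + 1)[1:]
    c_sum = np.bincount(flat, weights=cols.ravel(), minlength=n_labels + 1)[1:]
    ch_sum = [
        np.bincount(flat, weights=image[..., c].ravel().astype(float),
                    minlength=n_labels + 1)[1:]
        for c in range(3)
    ]
    slices = ndimage.find_objects(labels)
    objects: List[ObjectFeatures] = []
    for lab in range(1, n_labels + 1):
        area = int(areas[lab - 1])
        sl = slices[lab - 1]
        sub = labels[sl] == lab
        perim = trace_perimeter(sub)
        if area == 1:
            roundness = 1.0
        else:
            roundness = max(1.0, perim * perim / (4.0 * math.pi * area))
        objects.append(
            ObjectFeatures(
                label=lab,
                area=area,
                perimeter=perim,
                roundness=roundness,
                centroid=(r_sum[lab - 1] / area, c_sum[lab - 1] / area),
                mean_color=tuple(s[lab - 1] / area for s in ch_sum),
            )
        )
    return objects


def label_objects(
    mask: np.ndarray,
    image: np.ndarray,
    step_tag: StepTag = StepTag.WIDE,
    fill_holes: bool = False,
    exclude_border: bool = False,
) -> ObjectMap:
    """Label 8-connected components of ``mask`` and compute their features.

    Labels follow raster-scan order of first encounter. ``fill_holes`` fills
    interior holes before labeling; ``exclude_border`` drops objects touching
    the image edge.
    """
    img = as_rgb_image(image)
    m = np.asarray(mask, dtype=bool)
    if m.shape != img.shape[:2]:
        raise ValueError(
            f"mask shape {m.shape} does not match image shape {img.shape[:2]}"
        )
    if fill_holes:
        m = ndimage.binary_fill_holes(m, structure=None)
    labels, n = ndimage.label(m, structure=_STRUCT8)
    if exclude_border and n:
        border = np.unique(
            np.concatenate(
                [labels[0], labels[-1], labels[:, 0], labels[:, -1]]
            )
        )
        border = border[border > 0]
        if border.size:
            drop = np.isin(labels, border)
            labels[drop] = 0
            labels, _ = _compact_labels(labels)
            m = labels > 0
            n = labels.max()
    objects = _features_for(labels, img, int(n))
    return ObjectMap(mask=m, labels=labels, objects=objects, step_tag=step_tag)


def _compact_labels(labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Relabel 1..K preserving order; returns (new labels, old label per new)."""
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    lut[present] = np.arange(1, present.size + 1)
    return lut[labels], present


def filter_objects(omap: ObjectMap, mfilter: MorphFilter) -> ObjectMap:
    """Retain exactly the objects whose area and roundness lie in the
    filter's closed bands; labels are recompacted in scan order."""
    keep = [o for o in omap.objects if mfilter.accepts(o)]
    keep_labels = np.array([o.label for o in keep], dtype=omap.labels.dtype)
    if keep_labels.size == omap.n_objects:
        return ObjectMap(
            mask=omap.mask.copy(),
            labels=omap.labels.copy(),
            objects=list(omap.objects),
            step_tag=omap.step_tag,
        )
    lut = np.zeros(int(omap.labels.max()) + 1, dtype=omap.labels.dtype)
    lut[keep_labels] = np.arange(1, keep_labels.size + 1)
    new_labels = lut[omap.labels]
    new_objects = [
        replace(o, label=i + 1) for i, o in enumerate(keep)
    ]
    return ObjectMap(
        mask=new_labels > 0,
        labels=new_labels,
        objects=new_objects,
        step_tag=omap.step_tag,
    )
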