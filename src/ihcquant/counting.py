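"""Estimate nuclei counts from selected object areas.

The macros select positive objects that are either single nuclei or
clusters of touching nuclei. A cluster is recognised by its area exceeding
``cluster_factor`` times the mean single-nucleus area and contributes
``round(area / mean_area)`` nuclei (at least 2, rounding half away from
zero); a singleton contributes 1. The mean nucleus area is either fixed in
the configuration or estimated per image as the median area of near-round
objects.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from statistics import median

from .config import RunConfig
from .objects import ObjectMap

__all__ = [
    "Complexity",
    "CountResult",
    "estimate_mean_nucleus_area",
    "count_nuclei",
    "classify_complexity",
]

#: Roundness bound under which an object is trusted as a single nucleus
#: when estimating the mean nucleus area automatically.
ROUND_OBJECT_MAX_ROUNDNESS = 1.3


class Complexity(enum.Enum):
    LOW = "LOW"
    HIGH = "HIGH"


@dataclass(frozen=True)
class CountResult:
    n_objects: int
    n_singletons: int
    n_clusters: int
    estimated_nuclei: int
    mean_nucleus_area_used: float
    complexity: Complexity


def _round_half_away(x: float) -> int:
    """round-half-away-from-zero, immune to banker's rounding."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def estimate_mean_nucleus_area(objects: ObjectMap, cfg: RunConfig) -> float:
    """Mean single-nucleus area (px^2) to use for cluster splitting.

    A numeric ``cfg.mean_nucleus_area`` is passed through. With "auto", the
    median area of objects with roundness <= 1.3 is used — near-round
    objects are almost surely single nuclei — falling back to the
    configured default when no such object exists.
    """
    if not isinstance(cfg.mean_nucleus_area, str):
        return float(cfg.mean_nucleus_area)
    round_areas = [
        o.area for o in objects.objects if o.roundness <= ROUND_OBJECT_MAX_ROUNDNESS
    ]
    if not round_areas:
        return float(cfg.fallback_nucleus_area)
    return float(median(round_areas))


def count_nuclei(objects: ObjectMap, mean_area: float, cfg: RunConfig) -> CountResult:
    """Convert selected objects into an estimated number of positive nuclei."""
    if mean_area <= 0:
        raise ValueError(f"mean_area must be > 0, got {mean_area}")
    cluster_cut = cfg.cluster_factor * mean_area
    n_singletons = n_clusters = estimated = 0
    for obj in objects.objects:
        if obj.area > cluster_cut:
            n_clusters += 1
            estimated += max(2, _round_half_away(obj.area / mean_area))
        else:
            n_singletons += 1
            estimated += 1
    return CountResult(
        n_objects=objects.n_objects,
        n_singletons=n_singletons,
        n_clusters=n_clusters,
        estimated_nuclei=estimated,
        mean_nucleus_area_used=float(mean_area),
        complexity=classify_complexity(estimated, cfg.complexity_cutoff),
    )


def classify_complexity(estimated_nuclei: int, cutoff: int = 100) -> Complexity:
    """LOW for at most ``cutoff`` positive nuclei per image, HIGH above."""
    if estimated_nuclei < 0:
        raise ValueError("counts must be >= 0")
    return Complexity.LOW if estimated_nuclei <= cutoff else Complexity.HIGH
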