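"""Run configuration: color ranges, morphological bands and thresholds.

The procedure's numeric parameters (stain-class RGB boxes, per-step area and
roundness bands, the background-ratio cut, the cluster-splitting constants)
live in a YAML key-value file. Every key is optional; missing keys fall back
to the shipped defaults, which are calibrated to the palette of the synthetic
scene generator in :mod:`ihcquant.synthetic`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Mapping, Tuple, Union

import yaml

from .color import ColorRange
from .objects import MorphFilter

__all__ = ["RunConfig", "default_config", "load_config", "dump_config"]

#: Default stain-class boxes (RGB, inclusive). DAB brown is split into a
#: darkest, a mid and a light band; hematoxylin blue marks negative nuclei.
_DEF_DARKEST = ColorRange(40, 120, 20, 90, 0, 70)
_DEF_MID = ColorRange(121, 170, 80, 130, 40, 100)
_DEF_LIGHT = ColorRange(171, 215, 120, 170, 70, 135)
_DEF_NEGATIVE = ColorRange(60, 160, 70, 170, 130, 230)
#: Wide positive range: per-channel hull of the three brown bands
#: (darkest..lightest positive brown), used by the legacy no-background macro.
_DEF_WIDE = ColorRange.hull([_DEF_DARKEST, _DEF_MID, _DEF_LIGHT])
#: Background-discrimination ranges: bg1 is the wide positive range; bg2
#: extends the light band toward even lighter, washed-out brown.
_DEF_BG1 = _DEF_WIDE
_DEF_BG2 = ColorRange(171, 230, 120, 185, 70, 150)

_POSITIVE_KEYS = ("darkest", "mid", "light", "wide_positive")


def _default_ranges() -> Dict[str, ColorRange]:
    return {
        "darkest": _DEF_DARKEST,
        "mid": _DEF_MID,
        "light": _DEF_LIGHT,
        "negative": _DEF_NEGATIVE,
        "wide_positive": _DEF_WIDE,
        "bg1": _DEF_BG1,
        "bg2": _DEF_BG2,
    }


def _default_filters() -> Dict[str, MorphFilter]:
    step = MorphFilter(area_min=80, area_max=5000, roundness_min=1.0, roundness_max=3.0)
    return {
        "map1": step,
        "map2": step,
        "map3": step,
        # final step of the high-background macro: strictest band, keeps only
        # small round nucleus-like objects among the light-brown pixels
        "final": MorphFilter(area_min=80, area_max=1200,
                             roundness_min=1.0, roundness_max=1.6),
        # legacy wide macro: color segmentation with only a speck filter;
        # large clusters are kept and split by area in the counting step
        "wide": MorphFilter(area_min=80, area_max=math.inf,
                            roundness_min=1.0, roundness_max=math.inf),
    }


@dataclass(frozen=True)
class RunConfig:
    """Validated parameter set driving the whole pipeline."""

    ranges: Dict[str, ColorRange] = field(default_factory=_default_ranges)
    morph_filters: Dict[str, MorphFilter] = field(default_factory=_default_filters)
    sentinel_color: Tuple[int, int, int] = (0, 255, 0)
    ratio_threshold: float = 0.2
    mean_nucleus_area: Union[float, str] = "auto"
    fallback_nucleus_area: float = 450.0
    cluster_factor: float = 1.5
    complexity_cutoff: int = 100
    fill_holes: bool = False
    exclude_border: bool = False
    loa_multiplier: float = 1.96

    def __post_init__(self) -> None:
        missing = set(_default_ranges()) - set(self.ranges)
        if missing:
            raise ValueError(f"missing color ranges: {sorted(missing)}")
        missing_f = set(_default_filters()) - set(self.morph_filters)
        if missing_f:
            raise ValueError(f"missing morph filters: {sorted(missing_f)}")
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be > 0")
        if self.complexity_cutoff < 1:
            raise ValueError("complexity_cutoff must be >= 1")
        if self.cluster_factor <= 0:
            raise ValueError("cluster_factor must be > 0")
        if isinstance(self.mean_nucleus_area, str):
            if self.mean_nucleus_area != "auto":
                raise ValueError(
                    "mean_nucleus_area must be a positive number or 'auto'"
                )
        elif self.mean_nucleus_area <= 0:
            raise ValueError("mean_nucleus_area must be a positive number or 'auto'")
        for key in _POSITIVE_KEYS:
            if self.ranges[key].contains(self.sentinel_color):
                raise ValueError(
                    f"sentinel color {self.sentinel_color} lies inside the "
                    f"positive color range {key!r}"
                )


def default_config() -> RunConfig:
    return RunConfig()


def _parse_range(val: Any, key: str) -> ColorRange:
    if isinstance(val, Mapping):
        try:
            r, g, b = val["r"], val["g"], val["b"]
        except KeyError as exc:
            raise ValueError(f"color range {key!r} needs r, g and b entries") from exc
        return ColorRange(int(r[0]), int(r[1]), int(g[0]), int(g[1]),
                          int(b[0]), int(b[1]))
    if isinstance(val, (list, tuple)) and len(val) == 6:
        return ColorRange(*(int(v) for v in val))
    raise ValueError(f"cannot parse color range {key!r}: {val!r}")


def _parse_filter(val: Any, key: str) -> MorphFilter:
    if not isinstance(val, Mapping):
        raise ValueError(f"cannot parse morph filter {key!r}: {val!r}")
    area = val.get("area", (1, None))
    rnd = val.get("roundness", (1, None))

    def _num(v: Any, inf_if_none: bool) -> float:
        if v is None and inf_if_none:
            return math.inf
        return float(v)

    return MorphFilter(
        area_min=_num(area[0], False),
        area_max=_num(area[1], True),
        roundness_min=_num(rnd[0], False),
        roundness_max=_num(rnd[1], True),
    )


def load_config(path: Union[str, Path, None] = None) -> RunConfig:
    """Load a YAML configuration, filling unset keys with the defaults.

    ``None`` or an empty file yields the default configuration. Validation
    errors (a channel with lo > hi, a sentinel inside a positive range)
    raise ``ValueError``.
    """
    if path is None:
        return default_config()
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if data is None:
        return default_config()
    if not isinstance(data, Mapping):
        raise ValueError(f"configuration root must be a mapping, got {type(data)}")
    ranges = _default_ranges()
    for key, val in (data.get("color_ranges") or {}).items():
        if key not in ranges:
            raise ValueError(f"unknown color range {key!r}")
        ranges[key] = _parse_range(val, key)
    filters = _default_filters()
    for key, val in (data.get("morph_filters") or {}).items():
        if key not in filters:
            raise ValueError(f"unknown morph filter {key!r}")
        filters[key] = _parse_filter(val, key)
    kwargs: Dict[str, Any] = {"ranges": ranges, "morph_filters": filters}
    if "sentinel_color" in data:
        kwargs["sentinel_color"] = tuple(int(v) for v in data["sentinel_color"])
    for key, conv in (
        ("ratio_threshold", float),
        ("fallback_nucleus_area", float),
        ("cluster_factor", float),
        ("complexity_cutoff", int),
        ("fill_holes", bool),
        ("exclude_border", bool),
        ("loa_multiplier", float),
    ):
        if key in data:
            kwargs[key] = conv(data[key])
    if "mean_nucleus_area" in data:
        v = data["mean_nucleus_area"]
        kwargs["mean_nucleus_area"] = v if v == "auto" else float(v)
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    """Write a configuration as YAML; load_config(dump) is the identity."""

    def _rng(r: ColorRange) -> Dict[str, list]:
        return {"r": [r.r_lo, r.r_hi], "g": [r.g_lo, r.g_hi], "b": [r.b_lo, r.b_hi]}

    def _flt(f: MorphFilter) -> Dict[str, list]:
        return {
            "area": [f.area_min, None if math.isinf(f.area_max) else f.area_max],
            "roundness": [
                f.roundness_min,
                None if math.isinf(f.roundness_max) else f.roundness_max,
            ],
        }

    data = {
        "color_ranges": {k: _rng(v) for k, v in cfg.ranges.items()},
        "morph_filters": {k: _flt(v) for k, v in cfg.morph_filters.items()},
        "sentinel_color": list(cfg.sentinel_color),
        "ratio_threshold": cfg.ratio_threshold,
        "mean_nucleus_area": cfg.mean_nucleus_area,
        "fallback_nucleus_area": cfg.fallback_nucleus_area,
        "cluster_factor": cfg.cluster_factor,
        "complexity_cutoff": cfg.complexity_cutoff,
        "fill_holes": cfg.fill_holes,
        "exclude_border": cfg.exclude_border,
        "loa_multiplier": cfg.loa_multiplier,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
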