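"""ihcquant: automated quantification of IHC-stained positive nuclei.

Segments DAB-brown positive nuclei in brightfield RGB images, discriminates
images with spurious brown background from clean ones via a stain-area
ratio, routes each image to the appropriate segmentation macro, and
estimates nuclei counts from object areas. Includes a synthetic scene
generator with ground truth and method-agreement statistics
(Bland-Altman, cumulative-difference curves).
"""

from .agreement import (
    AgreementSummary,
    DifferenceCurve,
    bland_altman,
    difference_curve,
    paired_counts,
    stratified_compare,
)
from .color import (
    ColorRange,
    apply_sentinel_mask,
    mask_area,
    mask_union,
    segment_by_color,
)
from .config import RunConfig, default_config, dump_config, load_config
from .counting import (
    Complexity,
    CountResult,
    classify_complexity,
    count_nuclei,
    estimate_mean_nucleus_area,
)
from .io import read_count_table, read_image, write_count_table, write_image
from .objects import (
    MorphFilter,
    ObjectFeatures,
    ObjectMap,
    StepTag,
    compute_roundness,
    filter_objects,
    label_objects,
)
from .pipeline import (
    BackgroundAssessment,
    BackgroundClass,
    MacroName,
    MacroResult,
    analyze_image,
    assess_background,
    build_map1,
    build_maps23,
    run_full_macro,
    run_none_bg_macro,
    run_restrictive_macro,
)
from .synthetic import (
    Nucleus,
    NucleusClass,
    SyntheticScene,
    generate_scene,
    scene_ground_truth,
)

__version__ = "0.1.0"


def quantify_image(image, cfg=None):
    """Run the full procedure on one image and estimate the nuclei count.

    Returns ``(MacroResult, CountResult)``.
    """
    from .counting import count_nuclei as _count, estimate_mean_nucleus_area as _mean

    cfg = cfg or default_config()
    result = analyze_image(image, cfg)
    mean_area = _mean(result.selected, cfg)
    return result, _count(result.selected, mean_area, cfg)


__all__ = [name for name in dir() if not name.startswith("_")]
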