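"""Labeling, morphometry and morphological gating of candidate nuclei."""

import math

import numpy as np
import pytest

from ihcquant.objects import (
    MorphFilter,
    StepTag,
    compute_roundness,
    filter_objects,
    label_objects,
    trace_perimeter,
)

from conftest import random_image


def flood_fill_count(mask):
    """Independent 8-connectivity component count by explicit flood fill."""
    mask = mask.copy()
    count = 0
    while mask.any():
        count += 1
        seeds = [tuple(np.argwhere(mask)[0])]
        while seeds:
            r, c = seeds.pop()
            if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
                continue
            mask[r, c] = False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    seeds.append((r + dr, c + dc))
    return count


class TestLabeling:
    def test_empty_mask(self, rng):
        omap = label_objects(np.zeros((5, 5), bool), random_image(rng, 5, 5))
        assert omap.n_objects == 0 and not omap.mask.any()

    def test_single_pixel_object(self, rng):
        mask = np.zeros((5, 5), bool)
        mask[2, 3] = True
        omap = label_objects(mask, random_image(rng, 5, 5))
        (obj,) = omap.objects
        assert obj.area == 1 and obj.roundness == 1.0
        assert obj.centroid == (2.0, 3.0)

    def test_diagonal_pixels_are_one_object(self, rng):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        omap = label_objects(mask, random_image(rng, 4, 4))
        assert omap.n_objects == 1 == flood_fill_count(mask)

    def test_component_count_matches_flood_fill(self, rng):
        for _ in range(10):
            mask = rng.random((12, 12)) < 0.35
            omap = label_objects(mask, random_image(rng, 12, 12))
            assert omap.n_objects == flood_fill_count(mask)

    def test_object_areas_sum_to_mask_area(self, rng):
        mask = rng.random((20, 20)) < 0.4
        omap = label_objects(mask, random_image(rng, 20, 20))
        assert sum(o.area for o in omap.objects) == int(mask.sum())

    def test_translation_equivariance(self, rng):
        base = np.zeros((20, 20), bool)
        base[3:8, 4:9] = True
        base[5, 9] = True
        shifted = np.roll(base, (6, 5), axis=(0, 1))
        img = random_image(rng, 20, 20)
        c0 = label_objects(base, img).objects[0].centroid
        c1 = label_objects(shifted, img).objects[0].centroid
        assert c1 == (c0[0] + 6, c0[1] + 5)

    def test_labels_contiguous_and_match_mask(self, rng):
        mask = rng.random((15, 15)) < 0.3
        omap = label_objects(mask, random_image(rng, 15, 15))
        np.testing.assert_array_equal(omap.labels > 0, omap.mask)
        assert [o.label for o in omap.objects] == list(range(1, omap.n_objects + 1))


class TestRoundness:
    def test_disc_is_nearly_circular(self):
        """Rasterized disc of radius 20: roundness within digitization slack
        of the ideal circle value 1."""
        yy, xx = np.mgrid[0:60, 0:60]
        disc = (yy - 30) ** 2 + (xx - 30) ** 2 <= 20.5**2
        assert 1.00 <= compute_roundness(disc) <= 1.15

    def test_thin_line_is_far_from_circular(self):
        line = np.zeros((3, 52), bool)
        line[1, 1:51] = True
        # closed contour walk of a 1 x 50 strip has length 2 * 49 = 98
        assert trace_perimeter(line) == pytest.approx(98.0)
        assert compute_roundness(line) == pytest.approx(
            98.0**2 / (4 * math.pi * 50)
        )
        assert compute_roundness(line) > 5

    def test_rectangle_contour_length(self):
        rect = np.zeros((8, 10), bool)
        rect[2:7, 3:7] = True  # 5 x 4 pixels
        assert trace_perimeter(rect) == pytest.approx(2 * 4 + 2 * 3)

    def test_single_pixel_convention(self):
        px = np.zeros((3, 3), bool)
        px[1, 1] = True
        assert compute_roundness(px) == 1.0

    def test_clamped_below_at_one(self):
        two = np.zeros((3, 4), bool)
        two[1, 1:3] = True  # raw formula would give < 1
        assert compute_roundness(two) == 1.0


class TestMorphFilter:
    def test_invalid_bands_rejected(self):
        with pytest.raises(ValueError):
            MorphFilter(area_min=10, area_max=5)
        with pytest.raises(ValueError):
            MorphFilter(roundness_min=0.5)

    def test_permissive_filter_is_identity(self, rng):
        mask = rng.random((20, 20)) < 0.3
        omap = label_objects(mask, random_image(rng, 20, 20))
        out = filter_objects(omap, MorphFilter())
        np.testing.assert_array_equal(out.mask, omap.mask)
        assert [o.area for o in out.objects] == [o.area for o in omap.objects]

    def test_matches_brute_force_predicate(self, rng):
        mf = MorphFilter(area_min=3, area_max=40, roundness_min=1.0,
                         roundness_max=2.5)
        for _ in range(10):
            mask = rng.random((25, 25)) < 0.35
            omap = label_objects(mask, random_image(rng, 25, 25))
            out = filter_objects(omap, mf)
            expected = {
                (o.area, o.centroid)
                for o in omap.objects
                if 3 <= o.area <= 40 and 1.0 <= o.roundness <= 2.5
            }
            assert {(o.area, o.centroid) for o in out.objects} == expected

    def test_idempotent(self, rng):
        mf = MorphFilter(area_min=2, area_max=30, roundness_max=2.0)
        mask = rng.random((25, 25)) < 0.35
        omap = label_objects(mask, random_image(rng, 25, 25))
        once = filter_objects(omap, mf)
        twice = filter_objects(once, mf)
        np.testing.assert_array_equal(once.mask, twice.mask)
        assert [o.label for o in twice.objects] == [o.label for o in once.objects]

    def test_step_tag_preserved(self, rng):
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        omap = label_objects(mask, random_image(rng, 6, 6), step_tag=StepTag.MAP2)
        assert filter_objects(omap, MorphFilter()).step_tag is StepTag.MAP2
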