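"""Color-box segmentation, sentinel masking and mask algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ihcquant.color import (
    ColorRange,
    apply_sentinel_mask,
    mask_area,
    mask_union,
    segment_by_color,
)

from conftest import random_color_range, random_image


def brute_force_segment(image, cr):
    h, w, _ = image.shape
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            out[i, j] = cr.contains(image[i, j])
    return out


class TestColorRange:
    def test_rejects_lo_above_hi(self):
        with pytest.raises(ValueError):
            ColorRange(140, 60, 0, 255, 0, 255)

    def test_rejects_out_of_byte_bounds(self):
        with pytest.raises(ValueError):
            ColorRange(0, 300, 0, 255, 0, 255)

    def test_hull_contains_members(self):
        a = ColorRange(40, 120, 20, 90, 0, 70)
        b = ColorRange(171, 215, 120, 170, 70, 135)
        h = ColorRange.hull([a, b])
        assert (h.r_lo, h.r_hi) == (40, 215)
        assert h.contains((100, 60, 40)) and h.contains((200, 150, 100))


class TestSegmentByColor:
    def test_uniform_inclusion(self):
        img = np.full((6, 7, 3), (100, 60, 40), dtype=np.uint8)
        mask = segment_by_color(img, ColorRange(40, 120, 20, 90, 0, 70))
        assert mask.all() and mask_area(mask) == 42

    def test_uniform_exclusion_white(self):
        img = np.full((4, 4, 3), 255, dtype=np.uint8)
        mask = segment_by_color(img, ColorRange(40, 120, 20, 90, 0, 70))
        assert not mask.any()

    def test_matches_per_pixel_oracle(self, rng):
        for _ in range(25):
            img = random_image(rng)
            cr = random_color_range(rng)
            np.testing.assert_array_equal(
                segment_by_color(img, cr), brute_force_segment(img, cr)
            )

    def test_zero_pixel_image_rejected(self):
        with pytest.raises(ValueError):
            segment_by_color(np.empty((0, 4, 3), dtype=np.uint8),
                             ColorRange(0, 255, 0, 255, 0, 255))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(0, 2))
    def test_widening_a_bound_never_shrinks_area(self, seed, channel):
        """Monotonicity: enlarging the box can only add pixels."""
        r = np.random.default_rng(seed)
        img = random_image(r)
        cr = random_color_range(r)
        vals = [cr.r_lo, cr.r_hi, cr.g_lo, cr.g_hi, cr.b_lo, cr.b_hi]
        vals[2 * channel] = max(0, vals[2 * channel] - 20)
        vals[2 * channel + 1] = min(255, vals[2 * channel + 1] + 20)
        wider = ColorRange(*vals)
        a0 = mask_area(segment_by_color(img, cr))
        a1 = mask_area(segment_by_color(img, wider))
        assert a1 >= a0


class TestSentinelMask:
    def test_all_false_mask_is_identity(self, rng):
        img = random_image(rng, 5, 5)
        out = apply_sentinel_mask(img, np.zeros((5, 5), bool), (0, 255, 0))
        np.testing.assert_array_equal(out, img)

    def test_all_true_mask_yields_uniform_sentinel(self, rng):
        img = random_image(rng, 5, 5)
        out = apply_sentinel_mask(img, np.ones((5, 5), bool), (0, 255, 0))
        assert (out == np.array([0, 255, 0], dtype=np.uint8)).all()

    def test_idempotent_and_input_unmodified(self, rng):
        img = random_image(rng, 6, 4)
        before = img.copy()
        mask = np.zeros((6, 4), bool)
        mask[2:4, 1:3] = True
        once = apply_sentinel_mask(img, mask, (0, 255, 0))
        twice = apply_sentinel_mask(once, mask, (0, 255, 0))
        np.testing.assert_array_equal(once, twice)
        np.testing.assert_array_equal(img, before)

    def test_masked_pixels_leave_the_range(self, rng):
        """After sentinel displacement, the masked support no longer
        segments with any range excluding the sentinel."""
        img = random_image(rng, 8, 8)
        cr = ColorRange(40, 215, 20, 170, 0, 135)  # excludes (0, 255, 0)
        mask = segment_by_color(img, cr)
        out = apply_sentinel_mask(img, mask, (0, 255, 0))
        assert not (segment_by_color(out, cr) & mask).any()

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_sentinel_mask(random_image(rng), np.zeros((3, 3), bool), (0, 255, 0))


class TestMaskUnion:
    def test_self_union_idempotent(self, rng):
        m = rng.random((6, 6)) < 0.4
        np.testing.assert_array_equal(mask_union([m, m]), m)

    def test_disjoint_singletons_add(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert mask_area(mask_union([a, b])) == 2

    def test_matches_or_oracle_and_subadditive(self, rng):
        masks = [rng.random((7, 9)) < 0.5 for _ in range(4)]
        u = mask_union(masks)
        np.testing.assert_array_equal(u, masks[0] | masks[1] | masks[2] | masks[3])
        assert mask_area(u) <= sum(mask_area(m) for m in masks)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            mask_union([])
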