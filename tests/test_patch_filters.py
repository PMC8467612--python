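import numpy as np
import pytest

from conftest import eye_window_patch
from eyegt.geometry import Box
from eyegt.patch_filters import (
    BlackRuleConfig,
    EyePatch,
    RegionSpec,
    black_percentages,
    middle_region,
    pupil_reflection_check,
    ratio_map,
    ratio_map_score,
    score_patch,
)
from eyegt.quantize import BLACK, GRAY, WHITE
from oracles import bfs_components

W, H = 74, 69  # window size at the 1280x800 reference resolution


def make_patch(ternary):
    h, w = ternary.shape
    return EyePatch(ltx=0, lty=0, w=w, h=h, ternary=ternary)


def uniform_patch(value, w=W, h=H):
    return make_patch(np.full((h, w), value, dtype=np.uint8))


class TestMiddleRegion:
    @pytest.mark.parametrize(
        "w, h, expected",
        [
            (9, 9, Box(lx=3, rx=5, ty=3, by=5)),
            (74, 69, Box(lx=25, rx=48, ty=23, by=45)),
            (3, 3, Box(lx=1, rx=1, ty=1, by=1)),
        ],
    )
    def test_centered_floor_arithmetic(self, w, h, expected):
        box = middle_region(w, h)
        assert box == expected
        if (w, h) == (74, 69):
            assert (box.width, box.height) == (24, 23)

    def test_tiny_patch_rejected(self):
        with pytest.raises(ValueError):
            middle_region(2, 10)


class TestBlackPercentages:
    def test_all_black_patch(self):
        b1, b2, b3, ok = black_percentages(uniform_patch(BLACK))
        assert (b1, b2, b3) == (100.0, 100.0, 100.0)
        assert not ok  # b2 exceeds its default upper bound

    def test_all_white_patch_fails(self):
        b1, b2, b3, ok = black_percentages(uniform_patch(WHITE))
        assert (b1, b2, b3) == (0.0, 0.0, 0.0)
        assert not ok

    def test_zero_area_region_is_config_error(self):
        cfg = BlackRuleConfig(
            regions=(
                RegionSpec(kind="rect", x0=0.0, y0=0.0, x1=0.001, y1=0.001),
                RegionSpec(kind="rect"),
                RegionSpec(kind="rect"),
            ),
        )
        with pytest.raises(ValueError, match="zero area"):
            black_percentages(uniform_patch(BLACK, w=10, h=10), cfg)

    def test_true_eye_passes_and_skin_fails(self, open_frame, config):
        frame, truth = open_frame
        eye = eye_window_patch(frame, truth.left_pupil, config=config)
        *_, eye_ok = black_percentages(eye, config.black_rule)
        assert eye_ok
        # a pure-skin window on the cheek, well below the eye
        cheek_center = (truth.left_pupil[0] - 40, truth.left_pupil[1] + 120)
        cheek = eye_window_patch(frame, cheek_center, config=config)
        *_, cheek_ok = black_percentages(cheek, config.black_rule)
        assert not cheek_ok


class TestRatioMap:
    def test_wide_black_bar_marks_white(self):
        # every pixel of a 14x10 black bar has runs 14 (h) and 10 (v):
        # 1.4 > 1.3 so all of it flips to white in the map
        tern = np.full((20, 26), GRAY, dtype=np.uint8)
        tern[5:15, 6:20] = BLACK
        rmap = ratio_map(tern)
        assert np.all(rmap[5:15, 6:20] == WHITE)
        assert np.all(rmap[tern != BLACK] == BLACK)

    def test_ratio_exactly_threshold_stays_black(self):
        # 13 (h) vs 10 (v): 1.3 is not strictly greater than 1.3
        tern = np.full((20, 26), GRAY, dtype=np.uint8)
        tern[5:15, 6:19] = BLACK
        assert np.all(ratio_map(tern) == BLACK)

    def test_all_black_patch_scores_zero(self):
        # uniform runs of 74 (h) and 69 (v): ratio 1.07 < 1.3 everywhere
        patch = uniform_patch(BLACK)
        assert ratio_map_score(patch) == 0.0

    def test_invariant_under_white_gray_relabeling(self, rng):
        tern = rng.choice(
            np.array([BLACK, GRAY, WHITE], dtype=np.uint8), size=(30, 30)
        )
        swapped = tern.copy()
        swapped[tern == WHITE] = GRAY
        swapped[tern == GRAY] = WHITE
        assert np.array_equal(ratio_map(tern), ratio_map(swapped))

    def test_true_eye_scores_higher_than_offset_window(self, open_frame, config):
        frame, truth = open_frame
        centered = eye_window_patch(frame, truth.left_pupil, config=config)
        offset = eye_window_patch(frame, truth.left_pupil, offset=(0, 18),
                                  config=config)
        for p in (centered, offset):
            black_percentages(p, config.black_rule)
            ratio_map_score(p, config.ratio_threshold)
        assert centered.score > offset.score


class TestPupilReflectionCheck:
    def blob_patch(self, blob_w, blob_h, at=(35, 33)):
        tern = np.full((H, W), BLACK, dtype=np.uint8)
        x, y = at
        tern[y : y + blob_h, x : x + blob_w] = WHITE
        return make_patch(tern)

    @pytest.mark.parametrize(
        "blob, expected",
        [
            ((3, 1), False),  # 3 px: below the minimum count
            ((2, 2), True),   # 4 px: smallest acceptable glint
            ((4, 6), True),   # 24 px: largest acceptable glint
            ((5, 5), False),  # 25 px: too large
        ],
    )
    def test_pixel_count_bounds(self, blob, expected):
        has, spot = pupil_reflection_check(self.blob_patch(*blob))
        assert has is expected
        if expected:
            assert spot.pixel_count == blob[0] * blob[1]

    def test_isolated_blob_deep_in_black_passes(self):
        has, spot = pupil_reflection_check(self.blob_patch(3, 3))
        assert has and spot.pixel_count == 9
        assert spot.box == Box(lx=35, rx=37, ty=33, by=35)

    def test_blob_near_white_area_fails_margin(self):
        patch = self.blob_patch(3, 3, at=(35, 33))
        # white sclera-like area 2 px to the right of the blob's edge
        patch.ternary[20:50, 40:60] = WHITE
        has, _ = pupil_reflection_check(patch)
        assert not has

    def test_spot_outside_middle_region_ignored(self):
        has, _ = pupil_reflection_check(self.blob_patch(3, 3, at=(5, 5)))
        assert not has

    def test_first_passing_spot_in_raster_order(self):
        patch = self.blob_patch(2, 2, at=(30, 25))
        patch.ternary[40:42, 40:42] = WHITE  # second valid spot, later in raster
        has, spot = pupil_reflection_check(patch)
        assert has and spot.box.ty == 25

    def test_components_match_bfs_oracle(self, rng):
        for _ in range(50):
            tern = np.where(
                rng.random((H, W)) < 0.06, WHITE, BLACK
            ).astype(np.uint8)
            patch = make_patch(tern)
            has, spot = pupil_reflection_check(patch)
            # oracle: first raster-order component inside the middle region
            # meeting both the count and the margin conditions
            mid = middle_region(W, H)
            sub = (tern == WHITE)[mid.ty : mid.by + 1, mid.lx : mid.rx + 1]
            expected = None
            for pixels, (lx, rx, ty, by) in bfs_components(sub.tolist()):
                if not 4 <= len(pixels) <= 24:
                    continue
                box = Box(lx=lx + mid.lx, rx=rx + mid.lx,
                          ty=ty + mid.ty, by=by + mid.ty)
                cx, cy = (box.lx + box.rx) // 2, (box.ty + box.by) // 2
                probes = (
                    [(cx, box.ty - 1 - k) for k in range(3)]
                    + [(cx, box.by + 1 + k) for k in range(3)]
                    + [(box.lx - 1 - k, cy) for k in range(3)]
                    + [(box.rx + 1 + k, cy) for k in range(3)]
                )
                if all(
                    0 <= px < W and 0 <= py < H and tern[py, px] == BLACK
                    for px, py in probes
                ):
                    expected = box
                    break
            assert has is (expected is not None)
            if expected is not None:
                assert spot.box == expected

    def test_glint_found_in_synthetic_eye_patch(self, open_frame, config):
        frame, truth = open_frame
        patch = eye_window_patch(frame, truth.right_pupil, config=config)
        has, spot = pupil_reflection_check(patch)
        assert has and spot.pixel_count == 9


class TestScore:
    def test_score_is_sum_of_terms(self):
        patch = uniform_patch(BLACK)
        patch.b1, patch.b2, patch.b3, patch.r = 50.0, 60.0, 70.0, 20.0
        assert score_patch(patch) == 200.0

    def test_zero_terms_zero_score(self):
        patch = uniform_patch(BLACK)
        patch.b1 = patch.b2 = patch.b3 = patch.r = 0.0
        assert score_patch(patch) == 0.0

    def test_score_before_filters_is_an_error(self):
        patch = uniform_patch(BLACK)
        with pytest.raises(RuntimeError, match="before"):
            score_patch(patch)
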