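"""Adaptive progressive-window masking and the F/B metric."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shgquant import (
    EmptyMaskError,
    FBMask,
    MaskingParams,
    PhantomConfig,
    ProjectedPair,
    adaptive_window_threshold,
    adaptive_window_threshold_naive,
    build_masks,
    compute_fb,
    default_window_schedule,
    fb_fov_batch,
    fb_pipeline,
    generate_phantom,
    global_binarize,
)
from conftest import projected


class TestGlobalBinarize:
    def test_constant_image_all_ones(self):
        assert global_binarize(np.full((5, 5), 3.0), 0.6).all()

    def test_all_zero_image_all_zeros(self):
        assert not global_binarize(np.zeros((5, 5)), 0.6).any()

    def test_hand_worked_2x2(self):
        # mean 2.5, threshold 1.5: only the 10 passes
        img = np.array([[10.0, 0.0], [0.0, 0.0]])
        np.testing.assert_array_equal(
            global_binarize(img, 0.6), [[True, False], [False, False]]
        )

    def test_raising_factor_shrinks_seed(self, rng):
        img = rng.random((20, 20))
        masks = [global_binarize(img, f) for f in (0.4, 0.6, 0.9, 1.3)]
        for larger, smaller in zip(masks, masks[1:]):
            assert not (smaller & ~larger).any()


class TestParams:
    @pytest.mark.parametrize(
        "schedule", [(8, 3), (7, 7), (3, 7), (), (5, 4, 3), (7, 5, 1)]
    )
    def test_bad_schedules_rejected(self, schedule):
        with pytest.raises(ValueError):
            MaskingParams(window_schedule=schedule)

    def test_default_schedule_512(self):
        assert default_window_schedule((512, 512)) == (511, 255, 127, 63, 31, 15, 7, 3)


class TestAdaptiveThreshold:
    def test_constant_image_is_all_background(self):
        # local mean equals the pixel; strict inequality never fires
        img = np.full((16, 16), 4.0)
        out = adaptive_window_threshold(
            img, np.ones_like(img, bool), MaskingParams(window_schedule=(7, 3))
        )
        assert not out.any()

    def test_empty_seed_background_policy(self, rng):
        img = rng.random((16, 16))
        out = adaptive_window_threshold(
            img,
            np.zeros_like(img, bool),
            MaskingParams(window_schedule=(7, 3), nodata_policy="background"),
        )
        assert not out.any()

    def test_empty_seed_largest_window_policy(self, rng):
        img = np.asarray(rng.integers(0, 100, (16, 16)), float)
        out = adaptive_window_threshold(
            img,
            np.zeros_like(img, bool),
            MaskingParams(window_schedule=(15, 7, 3), nodata_policy="largest_window"),
        )
        naive = adaptive_window_threshold_naive(
            img,
            np.zeros_like(img, bool),
            MaskingParams(window_schedule=(15, 7, 3), nodata_policy="largest_window"),
        )
        assert out.any()  # the largest-window fallback thresholds every pixel
        np.testing.assert_array_equal(out, naive)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_double_loop_reference(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(16, 33, 2))
        img = np.asarray(rng.integers(0, 500, shape), float)
        params = MaskingParams(window_schedule=(15, 11, 7, 3))
        seed_mask = global_binarize(img, 0.6)
        fast = adaptive_window_threshold(img, seed_mask, params)
        slow = adaptive_window_threshold_naive(img, seed_mask, params)
        np.testing.assert_array_equal(fast, slow)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        img = np.asarray(rng.integers(0, 64, (16, 18)), float)
        seed_mask = rng.random((16, 18)) < 0.3
        params = MaskingParams(window_schedule=(9, 5, 3))
        np.testing.assert_array_equal(
            adaptive_window_threshold(img, seed_mask, params),
            adaptive_window_threshold_naive(img, seed_mask, params),
        )


class TestBuildMasks:
    def test_identical_channels_symmetric(self, rng):
        img = np.asarray(rng.integers(0, 200, (32, 32)), float)
        pair = ProjectedPair(f_img=img, b_img=img.copy())
        mask = build_masks(pair, MaskingParams(window_schedule=(15, 7, 3)))
        np.testing.assert_array_equal(mask.f_mask, mask.b_mask)
        np.testing.assert_array_equal(mask.combined, mask.f_mask)

    def test_zero_b_channel_absorbs(self, rng):
        pair = ProjectedPair(f_img=rng.random((24, 24)), b_img=np.zeros((24, 24)))
        mask = build_masks(pair, MaskingParams(window_schedule=(7, 3)))
        assert not mask.combined.any()

    def test_phantom_mask_covers_fibers_not_background(self, small_phantom):
        cfg, stack, truth = small_phantom
        pair = projected(cfg, stack)
        mask = build_masks(pair)
        fiber = truth.fiber_mask
        background = ~truth.rendered_mask  # pixels with no fiber signal at all
        coverage = (mask.combined & fiber).sum() / fiber.sum()
        false_pos = (mask.combined & background).sum() / background.sum()
        assert coverage >= 0.80
        assert false_pos <= 0.05


class TestComputeFB:
    def test_proportional_channels(self, rng):
        b = 1.0 + rng.random((16, 16))
        pair = ProjectedPair(f_img=2.0 * b, b_img=b)
        full = FBMask(f_mask=np.ones_like(b, bool), b_mask=np.ones_like(b, bool))
        res = compute_fb(pair, full)
        assert res.fb_value == pytest.approx(2.0, rel=1e-12)
        assert res.n_pixels == 256

    def test_identity_ratio(self, rng):
        b = 1.0 + rng.random((8, 8))
        pair = ProjectedPair(f_img=b.copy(), b_img=b)
        full = FBMask(f_mask=np.ones_like(b, bool), b_mask=np.ones_like(b, bool))
        assert compute_fb(pair, full).fb_value == pytest.approx(1.0)

    def test_empty_mask_raises(self, rng):
        b = 1.0 + rng.random((8, 8))
        pair = ProjectedPair(f_img=b, b_img=b)
        empty = FBMask(f_mask=np.zeros_like(b, bool), b_mask=np.zeros_like(b, bool))
        with pytest.raises(EmptyMaskError):
            compute_fb(pair, empty)

    def test_zero_b_pixels_excluded_not_infinite(self):
        f = np.full((4, 4), 8.0)
        b = np.full((4, 4), 4.0)
        b[0, 0] = 0.0
        pair = ProjectedPair(f_img=f, b_img=b)
        full = FBMask(f_mask=np.ones_like(b, bool), b_mask=np.ones_like(b, bool))
        res = compute_fb(pair, full)
        assert res.n_pixels == 15
        assert np.isfinite(res.fb_value)
        assert res.ratio_image[0, 0] == 0.0

    def test_phantom_recovery_single_seed(self, small_phantom):
        cfg, stack, truth = small_phantom
        res = fb_pipeline(
            stack,
            background_method="constant",
            background_f=cfg.background_f,
            background_b=cfg.background_b,
        )
        assert res.fb_value == pytest.approx(16.0, rel=0.05)


class TestScaleAndSwapInvariance:
    def test_scale_equivariance_power_of_two(self):
        # zero background; c = 2**k is exact in floating point, so masks
        # must be bit-identical and fb must scale exactly
        cfg = PhantomConfig(
            shape=(96, 96), n_fibers=5, fiber_length_range_px=(30, 60),
            background_f=0.0, background_b=0.0, seed=21,
        )
        stack, _ = generate_phantom(cfg)
        pair = projected(cfg, stack)
        mask = build_masks(pair)
        base = compute_fb(pair, mask)
        for c in (4.0, 0.25):
            scaled = ProjectedPair(f_img=c * pair.f_img, b_img=pair.b_img)
            mask_c = build_masks(scaled)
            np.testing.assert_array_equal(mask_c.combined, mask.combined)
            assert compute_fb(scaled, mask_c).fb_value == c * base.fb_value

    def test_swap_antisymmetry_proportional(self, rng):
        b = 1.0 + 10 * rng.random((32, 32))
        f = 3.0 * b
        pair = ProjectedPair(f_img=f, b_img=b)
        swapped = ProjectedPair(f_img=b, b_img=f)
        params = MaskingParams(window_schedule=(15, 7, 3))
        r1 = compute_fb(pair, build_masks(pair, params))
        r2 = compute_fb(swapped, build_masks(swapped, params))
        assert r2.fb_value == pytest.approx(1.0 / r1.fb_value, rel=1e-12)


class TestBatch:
    def _stacks(self, n_patients=1):
        out = []
        for p in range(n_patients):
            for region in ("TB", "TSI"):
                for roi in (1, 2, 3):
                    cfg = PhantomConfig(
                        shape=(64, 64), n_fibers=3, fiber_length_range_px=(20, 40),
                        seed=100 * p + 10 * (region == "TSI") + roi,
                    )
                    stack, _ = generate_phantom(cfg)
                    object.__setattr__(stack, "patient_id", f"p{p}")
                    object.__setattr__(stack, "region_label", region)
                    object.__setattr__(stack, "roi_index", roi)
                    out.append(stack)
        return out

    def test_row_counts(self):
        df = fb_fov_batch(self._stacks(), background_f=200.0, background_b=200.0)
        assert len(df) == 6
        assert set(df.region_label) == {"TB", "TSI"}

    def test_empty_input(self):
        assert fb_fov_batch([]).empty

    def test_batch_equals_composed_calls(self):
        stacks = self._stacks()
        df = fb_fov_batch(stacks, background_f=200.0, background_b=200.0)
        singles = [
            fb_pipeline(s, background_f=200.0, background_b=200.0).fb_value
            for s in stacks
        ]
        np.testing.assert_allclose(df.fb_value.to_numpy(), singles, rtol=0)

    def test_duplicate_keys_rejected(self):
        stacks = self._stacks()
        with pytest.raises(ValueError, match="duplicate"):
            fb_fov_batch(stacks + stacks[:1], background_f=200.0, background_b=200.0)
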