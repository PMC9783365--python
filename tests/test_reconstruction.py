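"""Shift-align-divide-smooth core: oracles and algebraic invariants."""

import numpy as np
import pytest
from scipy.signal import convolve2d

from spdri.exceptions import ValidationError
from spdri.model import LedSpec, ReflectanceFrame, Side
from spdri.reconstruction import (
    align_frames,
    compute_shift,
    run_spdri,
    smooth_map,
    spdri_divide,
)
from spdri.synthetic import (
    IlluminationModel,
    NoiseModel,
    PhantomSpec,
    generate_frame_pair,
    render_light_cone,
)

from conftest import gaussian_kernel_1d


def _frame(pixels, led_id=None):
    return ReflectanceFrame(pixels=np.asarray(pixels, float),
                            exposure_ms=100.0, led_id=led_id)


class TestComputeShift:
    def test_long_side_pair_shifts_in_x(self, instrument_leds):
        axis, shift = compute_shift(instrument_leds[1], instrument_leds[2])
        assert (axis, shift) == ("x", 1722 - 1875)

    def test_short_side_pair_shifts_in_y(self, instrument_leds):
        axis, shift = compute_shift(instrument_leds[4], instrument_leds[5])
        assert (axis, shift) == ("y", 2336 - 1947)

    def test_identical_leds_give_zero_shift(self, instrument_leds):
        axis, shift = compute_shift(instrument_leds[3], instrument_leds[3])
        assert (axis, shift) == ("x", 0)

    def test_mixed_sides_rejected(self, instrument_leds):
        with pytest.raises(ValidationError):
            compute_shift(instrument_leds[1], instrument_leds[4])


class TestAlignFrames:
    def test_zero_shift_is_identity_with_full_mask(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(1, 10, (6, 8)), rng.uniform(1, 10, (6, 8))
        out_a, out_b, mask = align_frames(_frame(a), _frame(b), "x", 0)
        assert np.array_equal(out_b, b)
        assert mask.all()

    def test_positive_x_shift_invalidates_leading_columns(self):
        b = np.ones((4, 10))
        _, shifted, mask = align_frames(_frame(np.ones((4, 10))), _frame(b), "x", 5)
        assert (~mask[:, :5]).all() and mask[:, 5:].all()

    @pytest.mark.parametrize("axis, shift", [("x", 3), ("x", -4), ("y", 2), ("y", -5)])
    def test_impulse_lands_at_index_arithmetic_position(self, axis, shift):
        b = np.zeros((12, 14))
        b[6, 7] = 1.0
        _, shifted, mask = align_frames(_frame(np.ones((12, 14))), _frame(b),
                                        axis, shift)
        expected = (6, 7 + shift) if axis == "x" else (6 + shift, 7)
        assert shifted[expected] == 1.0
        assert shifted.sum() == 1.0
        assert mask[expected]

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValidationError):
            align_frames(_frame(np.ones((4, 6))), _frame(np.ones((4, 6))), "x", 6)


class TestSpdriDivide:
    def test_self_division_is_unity(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(1, 100, (5, 5))
        m = spdri_divide(a, a, np.ones((5, 5), bool))
        np.testing.assert_array_equal(m.ratio, 1.0)

    def test_scalar_ratio(self):
        a = np.full((3, 3), 7.0)
        m = spdri_divide(a, 2 * a, np.ones((3, 3), bool))
        np.testing.assert_allclose(m.ratio, 0.5)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(1, 50, (4, 4)), rng.uniform(1, 50, (4, 4))
        m = spdri_divide(a, b, np.ones((4, 4), bool))
        oracle = np.array([[a[i, j] / b[i, j] for j in range(4)] for i in range(4)])
        np.testing.assert_array_equal(m.ratio, oracle)

    def test_zero_denominator_pixels_invalidated(self):
        a = np.ones((2, 2))
        b = np.array([[1.0, 0.0], [2.0, 4.0]])
        m = spdri_divide(a, b, np.ones((2, 2), bool))
        assert not m.valid_mask[0, 1]
        assert m.valid_mask.sum() == 3

    def test_counts_floor_masks_dim_pixels(self):
        a = np.array([[100.0, 3.0], [100.0, 100.0]])
        m = spdri_divide(a, a, np.ones((2, 2), bool), min_counts=10.0)
        assert not m.valid_mask[0, 1] and m.valid_mask.sum() == 3

    def test_empty_valid_region_rejected(self):
        with pytest.raises(ValidationError):
            spdri_divide(np.ones((2, 2)), np.zeros((2, 2)), np.ones((2, 2), bool))

    def test_reciprocity_on_shared_alignment(self):
        """Swapping numerator and denominator inverts the map exactly
        (to float round-off) at every jointly valid pixel."""
        rng = np.random.default_rng(3)
        a, b = rng.uniform(1, 1000, (40, 50)), rng.uniform(1, 1000, (40, 50))
        mask = np.ones((40, 50), bool)
        forward = spdri_divide(a, b, mask)
        backward = spdri_divide(b, a, mask)
        product = forward.ratio * backward.ratio
        assert np.max(np.abs(product - 1.0)) < 1e-14


class TestSmoothMap:
    def _map(self, ratio, mask=None):
        from spdri.model import SpdriMap

        if mask is None:
            mask = np.isfinite(ratio)
        return SpdriMap(ratio=ratio, valid_mask=mask, shift_axis="x", shift_px=1)

    def test_constant_map_unchanged(self):
        m = smooth_map(self._map(np.full((30, 30), 2.5)), sigma_px=5.0)
        np.testing.assert_allclose(m.ratio[m.valid_mask], 2.5, rtol=1e-12)

    def test_sigma_zero_returns_input_untouched(self):
        src = self._map(np.random.default_rng(0).uniform(1, 2, (8, 8)))
        out = smooth_map(src, sigma_px=0.0)
        assert out.ratio is src.ratio

    def test_impulse_matches_explicit_convolution_oracle(self):
        ratio = np.ones((64, 80))
        ratio[30, 40] += 1.0
        m = smooth_map(self._map(ratio), sigma_px=5.0)

        k1 = gaussian_kernel_1d(5.0)
        kernel = np.outer(k1, k1)
        num = convolve2d(ratio, kernel, mode="same", boundary="fill")
        den = convolve2d(np.ones_like(ratio), kernel, mode="same", boundary="fill")
        oracle = num / den
        np.testing.assert_allclose(m.ratio, oracle, rtol=1e-10, atol=1e-12)

    def test_masked_pixels_do_not_leak_into_valid_region(self):
        ratio = np.ones((40, 40))
        mask = np.ones((40, 40), bool)
        ratio[10:14, 10:14] = 1000.0
        mask[10:14, 10:14] = False  # huge values behind the mask
        out = smooth_map(self._map(np.where(mask, ratio, np.nan), mask), 3.0)
        np.testing.assert_allclose(out.ratio[out.valid_mask], 1.0, rtol=1e-12)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            smooth_map(self._map(np.ones((5, 5))), sigma_px=-1.0)


class TestRunSpdri:
    def test_identical_frames_zero_shift_give_unity_map(self, instrument_leds):
        led = instrument_leds[1]
        rng = np.random.default_rng(4)
        pixels = rng.uniform(100, 60000, (40, 2100))
        m = run_spdri(_frame(pixels, 1), _frame(pixels, 1), led, led, sigma_px=0.0)
        np.testing.assert_array_equal(m.ratio[m.valid_mask], 1.0)

    def test_illumination_invariance_under_scalar_gain(self, small_long_pair):
        led_a, led_b = small_long_pair
        rng = np.random.default_rng(5)
        a = rng.uniform(10, 500, (60, 400))
        b = rng.uniform(10, 500, (60, 400))
        base = run_spdri(_frame(a, 1), _frame(b, 2), led_a, led_b)
        gained = run_spdri(_frame(3.5 * a, 1), _frame(3.5 * b, 2), led_a, led_b)
        np.testing.assert_allclose(
            gained.ratio[gained.valid_mask], base.ratio[base.valid_mask], rtol=1e-12
        )

    def test_cone_cancels_for_zero_shift_any_cone_shape(self, small_long_pair):
        led_a, _ = small_long_pair
        cone = render_light_cone(IlluminationModel(led=led_a), 80, 400)
        m = run_spdri(cone, cone, led_a, led_a, sigma_px=0.0)
        np.testing.assert_array_equal(m.ratio[m.valid_mask], 1.0)

    def test_lower_numbered_led_is_numerator_regardless_of_order(
        self, small_long_pair
    ):
        led_a, led_b = small_long_pair
        rng = np.random.default_rng(6)
        a = rng.uniform(10, 500, (30, 400))
        b = rng.uniform(10, 500, (30, 400))
        m1 = run_spdri(_frame(a, 1), _frame(b, 2), led_a, led_b, sigma_px=0.0)
        m2 = run_spdri(_frame(b, 2), _frame(a, 1), led_b, led_a, sigma_px=0.0)
        assert m1.source_leds == m2.source_leds == (1, 2)
        np.testing.assert_array_equal(
            m1.ratio[m1.valid_mask], m2.ratio[m2.valid_mask]
        )

    def test_matches_straight_line_reimplementation(self, small_long_pair):
        """Full chain against an independent, loop-based rewrite of
        shift, divide and renormalized smoothing."""
        led_a, led_b = small_long_pair
        spec = PhantomSpec(
            thread_path=((170.0, 10.0), (170.0, 70.0)),
            thread_diameter_um=20.0,
            thread_depth_um=150.0,
        )
        fa, fb = generate_frame_pair(spec, led_a, led_b,
                                     noise=NoiseModel(kind="none"),
                                     height_px=80, width_px=400)
        sigma = 5.0
        m = run_spdri(fa, fb, led_a, led_b, sigma_px=sigma)

        # --- independent chain ---
        shift = int(round(led_a.position_px - led_b.position_px))  # x axis
        h, w = 80, 400
        shifted = np.zeros((h, w))
        mask = np.zeros((h, w), bool)
        for j in range(w):
            src = j - shift
            if 0 <= src < w:
                shifted[:, j] = fb.pixels[:, src]
                mask[:, j] = True
        mask &= (shifted > 0) & (fa.pixels > 0)
        ratio = np.where(mask, fa.pixels / np.where(mask, shifted, 1.0), 0.0)

        k1 = gaussian_kernel_1d(sigma)
        kernel = np.outer(k1, k1)
        num = convolve2d(ratio * mask, kernel, mode="same", boundary="fill")
        den = convolve2d(mask.astype(float), kernel, mode="same", boundary="fill")
        with np.errstate(invalid="ignore"):
            oracle = num / den

        np.testing.assert_allclose(
            m.ratio[m.valid_mask], oracle[mask], rtol=1e-10, atol=1e-12
        )
        assert np.array_equal(m.valid_mask, mask)

    def test_ratio_deviates_from_unity_only_near_thread(self, small_long_pair):
        led_a, led_b = small_long_pair
        spec = PhantomSpec(
            thread_path=((250.0, 10.0), (250.0, 110.0)),
            thread_diameter_um=20.0,
            thread_depth_um=150.0,
        )
        fa, fb = generate_frame_pair(spec, led_a, led_b,
                                     noise=NoiseModel(kind="none"),
                                     height_px=120, width_px=400)
        m = run_spdri(fa, fb, led_a, led_b, sigma_px=0.0)
        dev = np.abs(np.where(m.valid_mask, m.ratio, 1.0) - 1.0)
        # thread at x=250, its shifted copy 40 px away; outside that
        # neighbourhood (plus the depth blur's Gaussian tails) the ratio
        # must sit at 1
        near = np.zeros(400, bool)
        near[250 - 150: 250 + 140] = True
        assert dev[:, ~near].max() < 1e-6
        assert dev[:, near].max() > 0.05
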