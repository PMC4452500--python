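"""Per-offset cascade: pass-level oracles, engine equivalence, counter exactness."""

import numpy as np
import pytest

from nlmct.conventional import (
    PassState,
    accumulate_pass,
    diff_pass,
    finalize,
    nlm_filter_conventional,
    weight_pass,
)
from nlmct.core import NLMParams, OpCount, enumerate_offsets, gaussian_kernel, pad_symmetric
from nlmct.cost_model import conventional_complexity
from nlmct.reference import nlm_filter_naive, patch_distance, weight

from conftest import rel_max_diff


class TestDiffPass:
    def test_zero_offset_and_constant_image(self):
        img = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(diff_pass(img, (0, 0), B=1), np.zeros((5, 6)))
        np.testing.assert_array_equal(diff_pass(np.full((3, 4), 3.0), (2, 1), B=0), np.zeros((3, 4)))

    def test_ramp_matches_shift_oracle(self):
        img = np.add.outer(np.arange(4.0), np.arange(4.0))  # ramp
        got = diff_pass(img, (1, 0), B=0)
        padded = np.pad(img, 1, mode="symmetric")
        want = img - padded[1:5, 2:6]  # Y(p) - Y(p + (1,0)) with mirror at the right edge
        np.testing.assert_allclose(got, want, rtol=0, atol=0)

    def test_offset_beyond_radius_rejected(self):
        with pytest.raises(ValueError):
            diff_pass(np.zeros((4, 4)), (3, 0), B=1, T=2)


class TestWeightPass:
    def test_self_offset_gives_ones(self, rng):
        img = rng.uniform(0, 255, (5, 5))
        params = NLMParams(T=2, B=1, h=10)
        np.testing.assert_array_equal(
            weight_pass(img, (0, 0), gaussian_kernel(1), params), np.ones((5, 5))
        )

    def test_constant_image_marks_out_of_bounds_with_zero(self):
        img = np.full((4, 4), 9.0)
        params = NLMParams(T=2, B=1, h=10)
        U2 = weight_pass(img, (2, 1), gaussian_kernel(1), params)
        # partner in-bounds -> weight 1; out of bounds -> 0 marker
        assert set(np.unique(U2)) == {0.0, 1.0}
        assert U2[0, 0] == 1.0 and U2[0, 3] == 0.0 and U2[3, 0] == 0.0

    def test_matches_reference_weights(self, rng):
        img = rng.uniform(0, 255, (6, 6))
        params = NLMParams(T=3, B=1, h=10)
        off = (2, 1)
        U2 = weight_pass(img, off, gaussian_kernel(1), params)
        padded = pad_symmetric(img, 1)
        k = gaussian_kernel(1)
        for y in range(6):
            for x in range(6):
                qx, qy = x + off[0], y + off[1]
                if 0 <= qx < 6 and 0 <= qy < 6:
                    want = weight(patch_distance(padded, (x, y), (qx, qy), 1, k), 10.0, 1)
                    assert U2[y, x] == pytest.approx(want, rel=1e-12)
                else:
                    assert U2[y, x] == 0.0


class TestAccumulateAndFinalize:
    def test_unit_weights_at_self_offset(self, rng):
        img = rng.uniform(0, 255, (4, 4))
        state = PassState.zeros(4, 4)
        state.U2 = np.ones((4, 4))
        accumulate_pass(state, img, (0, 0))
        np.testing.assert_array_equal(state.U3, np.ones((4, 4)))
        np.testing.assert_array_equal(state.U4, img)

    def test_zero_weights_leave_state_unchanged(self, rng):
        img = rng.uniform(0, 255, (4, 4))
        state = PassState.zeros(4, 4)
        state.U2 = np.zeros((4, 4))
        accumulate_pass(state, img, (1, 1))
        np.testing.assert_array_equal(state.U3, 0)
        np.testing.assert_array_equal(state.U4, 0)

    def test_two_offsets_match_hand_accumulated_reference(self, rng):
        img = rng.uniform(0, 255, (4, 4))
        params = NLMParams(T=2, B=1, h=10)
        k = gaussian_kernel(1)
        state = PassState.zeros(4, 4)
        expected_U3 = np.zeros((4, 4))
        expected_U4 = np.zeros((4, 4))
        padded = pad_symmetric(img, 1)
        for off in [(1, 0), (-1, 2)]:
            state.U2 = weight_pass(img, off, k, params)
            accumulate_pass(state, img, off)
            for y in range(4):
                for x in range(4):
                    qx, qy = x + off[0], y + off[1]
                    if 0 <= qx < 4 and 0 <= qy < 4:
                        w = weight(patch_distance(padded, (x, y), (qx, qy), 1, k), 10.0, 1)
                        expected_U3[y, x] += w
                        expected_U4[y, x] += w * img[qy, qx]
        np.testing.assert_allclose(state.U3, expected_U3, rtol=1e-12)
        np.testing.assert_allclose(state.U4, expected_U4, rtol=1e-12)

    def test_finalize_divides_and_guards_zero(self, rng):
        img = rng.uniform(0, 255, (3, 3))
        state = PassState(None, None, U3=np.full((3, 3), 2.0), U4=2.0 * img)
        np.testing.assert_allclose(finalize(state), img, rtol=1e-15)
        with pytest.raises(RuntimeError):
            finalize(PassState.zeros(3, 3))


class TestConventionalEngine:
    def test_matches_naive_oracle(self, rng):
        img = rng.uniform(0, 255, (8, 8))
        params = NLMParams(T=2, B=1, h=10)
        assert rel_max_diff(nlm_filter_conventional(img, params), nlm_filter_naive(img, params)) < 1e-10

    def test_self_window_is_identity_with_unit_count(self):
        img = np.random.default_rng(5).uniform(0, 255, (4, 4))
        counter = OpCount()
        out = nlm_filter_conventional(img, NLMParams(T=0, B=1, h=10), counter=counter)
        np.testing.assert_allclose(out, img, rtol=1e-14)
        assert counter.charged_per_pixel == 1 * ((2 * 1 + 1) ** 2 + 2) + 1

    @pytest.mark.parametrize("T,B", [(0, 0), (1, 1), (2, 0), (3, 2), (4, 1)])
    def test_counter_equals_closed_form(self, rng, T, B):
        img = rng.uniform(0, 255, (5, 6))
        counter = OpCount()
        nlm_filter_conventional(img, NLMParams(T=T, B=B, h=10), counter=counter)
        assert counter.charged_per_pixel == conventional_complexity(T, B)

    def test_offset_chunking_does_not_change_the_result(self, rng):
        """Accumulation split into two chunks equals the single sweep (the
        'parallel pass' contract: results independent of internal chunking)."""
        img = rng.uniform(0, 255, (6, 6))
        params = NLMParams(T=2, B=1, h=10)
        k = gaussian_kernel(1)
        offsets = enumerate_offsets(2, "full")
        whole = PassState.zeros(6, 6)
        part_a, part_b = PassState.zeros(6, 6), PassState.zeros(6, 6)
        for i, off in enumerate(offsets):
            U2 = weight_pass(img, off, k, params)
            whole.U2 = U2
            accumulate_pass(whole, img, off)
            part = part_a if i % 2 == 0 else part_b
            part.U2 = U2
            accumulate_pass(part, img, off)
        np.testing.assert_allclose(whole.U3, part_a.U3 + part_b.U3, rtol=1e-13)
        np.testing.assert_allclose(whole.U4, part_a.U4 + part_b.U4, rtol=1e-13)

    def test_final_weight_sum_matches_reference_weights(self, rng):
        """State-plane conservation: U3 equals the sum of all in-bounds
        reference weights after the full offset loop."""
        img = rng.uniform(0, 255, (5, 5))
        params = NLMParams(T=2, B=1, h=10)
        k = gaussian_kernel(1)
        state = PassState.zeros(5, 5)
        for off in enumerate_offsets(2, "full"):
            state.U2 = weight_pass(img, off, k, params)
            accumulate_pass(state, img, off)
        padded = pad_symmetric(img, 1)
        for y in range(5):
            for x in range(5):
                total = sum(
                    weight(patch_distance(padded, (x, y), (qx, qy), 1, k), 10.0, 1)
                    for qy in range(max(0, y - 2), min(5, y + 3))
                    for qx in range(max(0, x - 2), min(5, x + 3))
                )
                assert state.U3[y, x] == pytest.approx(total, rel=1e-12)
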