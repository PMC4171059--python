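"""Form pathway: Gabor dictionary, whitening, SSA, match scoring."""

import numpy as np
import pytest

import biomotion as bm
from biomotion import form_pathway as fp


class TestBuildDictionary:
    @pytest.mark.parametrize(
        "n,m,expected_count", [(8, 1, 8), (1, 1, 1), (8, 2, 16), (4, 3, 12)]
    )
    def test_kernel_count_and_thetas(self, n, m, expected_count):
        d = bm.build_dictionary(n, m, 17)
        assert sum(1 for _ in d.iter_kernels()) == expected_count
        np.testing.assert_allclose(d.thetas, np.arange(n) * np.pi / n)
        assert np.all(d.thetas >= 0) and np.all(d.thetas < np.pi)

    def test_kernels_zero_mean_unit_norm(self, gdict8):
        for _, _, k in gdict8.iter_kernels():
            assert abs(k.real.mean()) < 1e-12
            assert abs(k.imag.mean()) < 1e-12
            assert np.sqrt((np.abs(k) ** 2).sum()) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("bad", [dict(n_orientations=0, n_scales=1),
                                     dict(n_orientations=1, n_scales=0)])
    def test_nonpositive_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            bm.build_dictionary(base_size=17, **bad)

    def test_even_base_size_rejected(self):
        with pytest.raises(ValueError):
            bm.build_dictionary(8, 1, 16)


class TestConvolveBank:
    def test_zero_image_zero_responses(self, gdict8):
        stack = bm.convolve_bank(np.zeros((16, 16)), gdict8)
        assert np.all(stack.as_array() == 0)

    def test_full_convolution_shape(self):
        d = bm.build_dictionary(4, 1, 5)
        stack = bm.convolve_bank(np.ones((10, 10)), d)
        assert (stack.height, stack.width) == (14, 14)

    def test_matches_direct_double_sum(self, gdict8):
        """FFT responses equal the brute-force convolution sum to 1e-8."""
        rng = np.random.default_rng(5)
        img = rng.standard_normal((16, 16))
        stack = bm.convolve_bank(img, gdict8)
        kern = gdict8.kernels[0][3]
        # direct double-sum at a handful of lattice points
        for r, c in [(10, 10), (16, 16), (20, 7)]:
            direct = 0.0 + 0.0j
            for i in range(17):
                for j in range(17):
                    ri, cj = r - i, c - j
                    if 0 <= ri < 16 and 0 <= cj < 16:
                        direct += kern[i, j] * img[ri, cj]
            assert abs(stack.raw[0][3][r, c] - direct) < 1e-8

    def test_non_finite_rejected(self, gdict8):
        img = np.zeros((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            bm.convolve_bank(img, gdict8)


class TestSigmoidWhiten:
    def test_bounded_and_zero_maps_to_zero(self, gdict8):
        rng = np.random.default_rng(0)
        stack = bm.convolve_bank(rng.standard_normal((16, 16)), gdict8)
        out = bm.sigmoid_whiten(stack, saturation=6.0).as_array()
        assert out.min() >= 0.0 and out.max() <= 6.0
        zero = bm.sigmoid_whiten(bm.convolve_bank(np.zeros((16, 16)), gdict8))
        assert np.all(zero.as_array() == 0)

    def test_uniform_map_transforms_uniformly(self, gdict8):
        stack = bm.convolve_bank(np.zeros((16, 16)), gdict8)
        for k in range(8):
            stack.responses[0][k][:] = 2.0
        out = bm.sigmoid_whiten(stack).as_array()
        assert np.ptp(out) == 0.0
        # closed form: local mean equals the value itself -> tanh(1)
        assert out.flat[0] == pytest.approx(6.0 * np.tanh(1.0))

    def test_monotone_in_magnitude_at_fixed_energy(self, gdict8):
        stack = bm.convolve_bank(np.zeros((32, 32)), gdict8)
        for k in range(8):
            stack.responses[0][k][:] = 1.0
        stack.responses[0][0][20, 20] = 3.0
        stack.responses[0][0][20, 28] = 2.0
        out = bm.sigmoid_whiten(stack)
        assert out.responses[0][0][20, 20] > out.responses[0][0][20, 28]

    def test_rejects_nonpositive_saturation(self, gdict8):
        stack = bm.convolve_bank(np.zeros((16, 16)), gdict8)
        with pytest.raises(ValueError):
            bm.sigmoid_whiten(stack, saturation=0.0)


class TestLocalMaxResponse:
    def _stack_with_map(self, gdict8, arr):
        stack = bm.convolve_bank(np.zeros((16, 16)), gdict8)
        for k in range(8):
            stack.responses[0][k][:] = 0.0
        stack.responses[0][0][: arr.shape[0], : arr.shape[1]] = arr
        return stack

    def test_single_peak_found(self, gdict8):
        arr = np.zeros((9, 9))
        arr[4, 5] = 3.0
        stack = self._stack_with_map(gdict8, arr)
        el = fp.GaborElement(4, 4, 0, 0, 0.0, 0.1)
        val, pos = bm.local_max_response(stack, el, 2, 0)
        assert val == 3.0 and pos == (4, 5, 0)

    def test_constant_map_tie_breaks_lexicographically(self, gdict8):
        stack = bm.convolve_bank(np.zeros((16, 16)), gdict8)
        for k in range(8):
            stack.responses[0][k][:] = 1.5
        el = fp.GaborElement(10, 10, 2, 0, 0.0, 0.1)
        val, pos = bm.local_max_response(stack, el, 2, 1)
        assert val == 1.5
        assert pos == (8, 8, 1)  # smallest (row, col, orientation)

    def test_equals_exhaustive_enumeration(self, gdict8):
        rng = np.random.default_rng(3)
        stack = bm.convolve_bank(rng.standard_normal((16, 16)), gdict8)
        sw = bm.sigmoid_whiten(stack)
        el = fp.GaborElement(12, 14, 3, 0, 0.0, 0.1)
        val, _ = bm.local_max_response(sw, el, 2, 1)
        brute = max(
            sw.responses[0][k][r, c]
            for k in (2, 3, 4)
            for r in range(10, 15)
            for c in range(12, 17)
        )
        assert val == pytest.approx(brute, abs=1e-12)

    def test_off_lattice_rejected(self, gdict8):
        stack = bm.convolve_bank(np.zeros((16, 16)), gdict8)
        el = fp.GaborElement(500, 500, 0, 0, 0.0, 0.1)
        with pytest.raises(ValueError):
            bm.local_max_response(stack, el, 2, 1)


class TestSSATrain:
    def test_recovers_bar_orientation(self, gdict8):
        """One vertical bar -> the single selected element is vertical."""
        bar = bm.make_bar_image(0.0, length=20, width=3, shape=(32, 32))
        tpl = bm.ssa_train([bar], gdict8, 1)
        assert len(tpl) == 1
        el = tpl.elements[0]
        assert el.orientation_index == 0
        # position on the bar (lattice includes 8-pixel padding)
        assert abs(el.col - (15.5 + 8)) <= 3

    def test_zero_elements_empty_template(self, gdict8):
        bar = bm.make_bar_image(0.0, shape=(32, 32))
        tpl = bm.ssa_train([bar], gdict8, 0)
        assert len(tpl) == 0

    def test_plus_shape_selects_both_orientations(self, gdict8):
        plus = bm.make_bar_image(0.0, 14, 3) + bm.make_bar_image(np.pi / 2, 14, 3)
        tpl = bm.ssa_train([plus, plus], gdict8, 2)
        assert sorted(e.orientation_index for e in tpl.elements) == [0, 4]

    def test_inhibition_distance_respected(self, gdict8):
        rng = np.random.default_rng(1)
        img = rng.standard_normal((32, 32))
        tpl = bm.ssa_train([img], gdict8, 6)
        rad = gdict8.kernel_half_size[0]
        for i, a in enumerate(tpl.elements):
            for b in tpl.elements[i + 1 :]:
                close = (a.row - b.row) ** 2 + (a.col - b.col) ** 2 < rad**2
                dori = min(
                    abs(a.orientation_index - b.orientation_index),
                    8 - abs(a.orientation_index - b.orientation_index),
                )
                assert not (close and dori <= 1)

    def test_selects_min_of_k_and_candidates(self, gdict8):
        bar = bm.make_bar_image(0.0, 20, 3, shape=(32, 32))
        assert len(bm.ssa_train([bar], gdict8, 4)) == 4

    def test_empty_image_list_rejected(self, gdict8):
        with pytest.raises(ValueError):
            bm.ssa_train([], gdict8, 1)

    def test_uniform_flow_prior_is_identity(self, gdict8):
        bar = bm.make_bar_image(np.pi / 4, 20, 3, shape=(32, 32), noise=0.05, seed=2)
        t_none = bm.ssa_train([bar], gdict8, 3)
        t_unif = bm.ssa_train([bar], gdict8, 3, flow_prior=np.ones((32, 32)))
        assert [(e.row, e.col, e.orientation_index) for e in t_none.elements] == [
            (e.row, e.col, e.orientation_index) for e in t_unif.elements
        ]
        np.testing.assert_allclose(t_none.weights, t_unif.weights)

    def test_flow_prior_steers_selection(self, gdict8):
        """Zero prior over one bar forces selection onto the other."""
        img = bm.make_bar_image(0.0, 14, 3) + bm.make_bar_image(np.pi / 2, 14, 3)
        prior = np.zeros((32, 32))
        prior[13:19, :12] = 1.0  # left arm of the horizontal bar only
        tpl = bm.ssa_train([img], gdict8, 1, flow_prior=prior)
        assert tpl.elements[0].orientation_index == 4


class TestMatchScore:
    def test_empty_template_scores_zero(self, gdict8):
        stack = bm.sigmoid_whiten(bm.convolve_bank(np.zeros((16, 16)), gdict8))
        tpl = fp.ActiveBasisTemplate(n_orientations=8, n_scales=1)
        assert bm.match_score(tpl, stack) == 0.0

    def test_training_image_outscores_blank(self, gdict8):
        bar = bm.make_bar_image(0.0, 20, 3, shape=(32, 32))
        tpl = bm.ssa_train([bar], gdict8, 3)
        s_bar = bm.match_score(tpl, bm.sigmoid_whiten(bm.convolve_bank(
            bm.normalize_frame(bar), gdict8)))
        s_blank = bm.match_score(tpl, bm.sigmoid_whiten(bm.convolve_bank(
            np.zeros((32, 32)), gdict8)))
        assert s_bar >= s_blank

    def test_additive_over_elements(self, gdict8):
        bar = bm.make_bar_image(np.pi / 4, 20, 3, shape=(32, 32), noise=0.05, seed=4)
        tpl = bm.ssa_train([bar], gdict8, 4)
        stack = bm.sigmoid_whiten(bm.convolve_bank(bm.normalize_frame(bar), gdict8))
        total = bm.match_score(tpl, stack)
        per_term = sum(
            delta * bm.local_max_response(stack, el, tpl.perturb_radius,
                                          tpl.perturb_orient)[0] - lz
            for el, delta, lz in zip(tpl.elements, tpl.weights, tpl.log_z)
        )
        assert total == pytest.approx(per_term, abs=1e-10)

    def test_translation_invariance_within_perturb_radius(self, gdict8):
        bar = bm.make_bar_image(0.0, 16, 3, shape=(40, 40))
        tpl = bm.ssa_train([bar], gdict8, 2)
        s0 = bm.match_score(tpl, bm.sigmoid_whiten(bm.convolve_bank(
            bm.normalize_frame(bar), gdict8)))
        shifted = np.roll(bar, (2, 2), axis=(0, 1))
        s1 = bm.match_score(tpl, bm.sigmoid_whiten(bm.convolve_bank(
            bm.normalize_frame(shifted), gdict8)))
        assert s1 == pytest.approx(s0, rel=0.02)

    def test_dictionary_mismatch_rejected(self, gdict8):
        d4 = bm.build_dictionary(4, 1, 17)
        stack4 = bm.sigmoid_whiten(bm.convolve_bank(np.zeros((16, 16)), d4))
        bar = bm.make_bar_image(0.0, 20, 3, shape=(32, 32))
        tpl = bm.ssa_train([bar], gdict8, 1)
        with pytest.raises(ValueError):
            bm.match_score(tpl, stack4)


class TestTemplateSerialization:
    def test_bit_exact_round_trip(self, gdict8, tmp_path):
        bar = bm.make_bar_image(np.pi / 8, 20, 3, shape=(32, 32), noise=0.03, seed=9)
        tpl = bm.ssa_train([bar], gdict8, 5)
        path = tmp_path / "template.zip"
        fp.save_template(tpl, path)
        back = fp.load_template(path)
        assert back.elements == tpl.elements
        assert back.weights == tpl.weights
        assert back.lambdas == tpl.lambdas
        assert back.log_z == tpl.log_z
        assert (back.perturb_radius, back.perturb_orient) == (
            tpl.perturb_radius, tpl.perturb_orient)
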