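"""Weight fields and the four estimators, checked against direct-sum oracles."""

import numpy as np
import pytest

from nlmdct.filters import filter_image, unbias, weight_map, weights_dct, weights_full
from nlmdct.image import FilterParams, PatchSpec, SearchSpec, pad_reflect
from nlmdct.reference import filter_image_naive

P3S5 = dict(patch=PatchSpec(3), search=SearchSpec(5))


def _padded(img, params):
    return pad_reflect(img, params.pad), params.pad


class TestWeightFields:
    def test_constant_image_uniform_weights(self):
        params = FilterParams(method="nlm", h=2.0, **P3S5)
        A, p = _padded(np.full((10, 10), 9.0), params)
        for fn in (weights_full, weights_dct):
            field = fn(A, (p + 4, p + 4), params)
            np.testing.assert_allclose(field.weights, 1 / 25, atol=1e-12)

    def test_huge_h_flattens_weights(self, rng):
        img = rng.uniform(0, 255, (12, 12))
        params = FilterParams(method="nlm", h=1e12, **P3S5)
        A, p = _padded(img, params)
        field = weights_full(A, (p + 6, p + 6), params)
        np.testing.assert_allclose(field.weights, 1 / 25, atol=1e-9)

    def test_weights_normalised_and_bounded(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        params = FilterParams(method="nlm-dct", h=30.0, d=6, **P3S5)
        A, p = _padded(img, params)
        for c in [(p, p), (p + 7, p + 3), (p + 15, p + 15)]:
            field = weights_dct(A, c, params)
            assert abs(field.weights.sum() - 1.0) < 1e-12
            assert field.weights.min() >= 0 and field.weights.max() <= 1

    def test_weights_match_direct_eq2_evaluation(self, rng):
        # independent double-loop evaluation of the weight definition
        img = rng.uniform(0, 1, (16, 16))
        params = FilterParams(method="nlm", h=10.0, **P3S5)
        A, p = _padded(img, params)
        c = (p + 8, p + 5)
        field = weights_full(A, c, params)
        expected = []
        for dy in range(-2, 3):
            for dx in range(-2, 3):
                jy, jx = c[0] + dy, c[1] + dx
                D2 = sum(
                    (A[c[0] + ky, c[1] + kx] - A[jy + ky, jx + kx]) ** 2
                    for ky in (-1, 0, 1)
                    for kx in (-1, 0, 1)
                )
                expected.append(np.exp(-D2 / 100.0))
        expected = np.array(expected) / np.sum(expected)
        np.testing.assert_allclose(field.weights, expected, atol=1e-12)

    def test_dct_full_dimension_equals_full_space_weights(self, rng):
        img = rng.uniform(0, 255, (14, 14))
        base = dict(h=40.0, **P3S5)
        pf = FilterParams(method="nlm", **base)
        pd = FilterParams(method="nlm-dct", d=9, **base)
        A, p = _padded(img, pf)
        c = (p + 7, p + 7)
        np.testing.assert_allclose(
            weights_dct(A, c, pd).weights, weights_full(A, c, pf).weights, atol=1e-9
        )

    def test_equal_dc_patches_at_d1_share_weight(self):
        # two patches differing by a zero-mean pattern have identical DC
        img = np.zeros((11, 11))
        img[4:7, 7] = [1.0, 0.0, -1.0]  # zero-mean column centred in the patch at (5, 7)
        img += 5.0
        params = FilterParams(method="nlm-dct", h=0.5, d=1, **P3S5)
        A, p = _padded(img, params)
        c = (p + 5, p + 5)
        w = weights_dct(A, c, params).as_window(5)
        # the patch two columns right has the same DC, hence the self-weight
        assert w[2, 4] == pytest.approx(w[2, 2], abs=1e-12)


class TestFilterImage:
    @pytest.mark.parametrize("method", ["nlm", "nlm-dct"])
    def test_constant_image_is_fixed_point(self, method):
        img = np.full((12, 12), 77.0)
        params = FilterParams(method=method, h=3.0, d=4, **P3S5)
        res = filter_image(img, params)
        np.testing.assert_allclose(res.denoised, 77.0, atol=1e-12)
        np.testing.assert_allclose(res.residual, 0.0, atol=1e-12)

    @pytest.mark.parametrize("method, d", [("nlm", None), ("nlm-dct", 5)])
    def test_output_within_window_bounds(self, rng, method, d):
        img = rng.uniform(0, 255, (20, 20))
        params = FilterParams(method=method, h=25.0, d=d, **P3S5)
        out = filter_image(img, params).denoised
        A = pad_reflect(img, params.search.half)
        sh = params.search.half
        for y in range(20):
            for x in range(20):
                win = A[y : y + 2 * sh + 1, x : x + 2 * sh + 1]
                assert win.min() - 1e-9 <= out[y, x] <= win.max() + 1e-9

    def test_residual_plus_denoised_reconstructs_input(self, rng):
        img = rng.uniform(0, 100, (16, 16))
        params = FilterParams(method="unlm", h=20.0, sigma=5.0, **P3S5)
        res = filter_image(img, params)
        np.testing.assert_array_equal(res.residual + res.denoised, img)

    @pytest.mark.parametrize(
        "method, d, sigma",
        [("nlm", None, None), ("nlm-dct", 5, None), ("unlm", None, 0.1), ("unlm-dct", 7, 0.1)],
    )
    def test_matches_naive_oracle(self, rng, method, d, sigma):
        img = rng.uniform(0, 1, (16, 16))
        params = FilterParams(method=method, h=0.5, d=d, sigma=sigma, **P3S5)
        fast = filter_image(img, params).denoised
        naive = filter_image_naive(img, params).denoised
        assert np.abs(fast - naive).max() < 1e-12

    def test_center_weight_max_heuristic_matches_oracle(self, rng):
        img = rng.uniform(0, 1, (12, 12))
        params = FilterParams(method="nlm", h=0.4, center_weight="max", **P3S5)
        fast = filter_image(img, params).denoised
        naive = filter_image_naive(img, params).denoised
        assert np.abs(fast - naive).max() < 1e-12

    def test_dct_with_full_dimension_equals_plain_nlm(self, rng):
        img = rng.uniform(0, 20, (32, 32))
        base = dict(h=50.0, patch=PatchSpec(5), search=SearchSpec(11))
        out_nlm = filter_image(img, FilterParams(method="nlm", **base)).denoised
        out_dct = filter_image(img, FilterParams(method="nlm-dct", d=25, **base)).denoised
        assert np.abs(out_nlm - out_dct).max() < 1e-9

    def test_negative_image_rejected(self):
        with pytest.raises(ValueError):
            filter_image(np.full((8, 8), -1.0), FilterParams(method="nlm", h=1.0, **P3S5))


class TestUnbias:
    @pytest.mark.parametrize(
        "value, sigma, expected",
        [
            (0.0, 5.0, 0.0),
            (5.0, 10.0, 0.0),
            (10.0, 1.0, np.sqrt(98.0)),
            (42.0, 0.0, 42.0),
        ],
    )
    def test_scalar_examples(self, value, sigma, expected):
        assert unbias(value, sigma) == pytest.approx(expected, abs=1e-12)

    def test_monotone_and_clamped(self):
        u = np.linspace(0, 20, 200)
        out = unbias(u, 3.0)
        assert np.all(np.diff(out) >= 0)
        assert np.all(out[u * u <= 18.0] == 0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            unbias(1.0, -1.0)


class TestWeightMap:
    def test_constant_image_uniform_map(self):
        params = FilterParams(method="nlm", h=1.0, **P3S5)
        w = weight_map(np.full((10, 10), 4.0), (5, 5), params)
        np.testing.assert_allclose(w, 1 / 25, atol=1e-12)

    def test_sums_to_one_and_center_maximal(self, rng):
        img = rng.uniform(0, 255, (15, 15))
        params = FilterParams(method="nlm-dct", h=30.0, d=6, **P3S5)
        w = weight_map(img, (7, 7), params)
        assert w.shape == (5, 5)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert w[2, 2] == w.max()

    def test_log_scale_is_log_of_weights(self, rng):
        img = rng.uniform(0, 50, (12, 12))
        params = FilterParams(method="nlm", h=20.0, **P3S5)
        w = weight_map(img, (6, 6), params)
        lw = weight_map(img, (6, 6), params, log_scale=True)
        np.testing.assert_allclose(lw, np.log(w), atol=1e-12)
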