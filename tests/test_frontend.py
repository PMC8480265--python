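import numpy as np
import pytest

from earlyvis import frontend, synthetic
from earlyvis.frontend import (build_lgn_bank, dog_filter_patch, fit_pca,
                               latency_encode, whiten_image, whitening_gain)


class TestWhitening:
    def test_constant_image_maps_to_zero(self):
        out = whiten_image(np.full((32, 32), 7.0), px_per_deg=5.0)
        assert np.max(np.abs(out)) < 1e-12

    def test_gain_at_cutoff_matches_closed_form(self):
        # H(f0) = f0 * e^-1 ~ 3.679 for f0 = 10 cycles/deg
        assert np.isclose(whitening_gain(10.0, f0=10.0), 10.0 * np.exp(-1))

    def test_sinusoid_amplification_follows_gain_and_squares_on_reapplication(self):
        n, ppd, f = 100, 5.0, 0.5
        x = np.arange(n) / ppd
        im = np.sin(2 * np.pi * f * x)[None, :] * np.ones((n, 1))
        g = whitening_gain(f, 10.0)
        once = whiten_image(im, ppd)
        twice = whiten_image(once, ppd)
        np.testing.assert_allclose(once, g * im, atol=1e-8)
        np.testing.assert_allclose(twice, g**2 * im, atol=1e-8)

    def test_flattens_pink_spectrum(self):
        im = synthetic.gen_pink_noise_images(1, 20, 5, 1.0, seed=0).images[0]
        slope = synthetic.spectral_slope(whiten_image(im, 5.0), 5.0)
        assert abs(slope) < 0.15

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            whiten_image(np.zeros((10, 12)), 5.0)


class TestPCA:
    def test_components_align_with_planted_variance_axes(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4000, 6)) * np.array([5.0, 3.0, 0.1, 0.1, 0.1, 0.1])
        t = fit_pca(X, d=2)
        assert abs(t.components[0, 0]) > 0.99
        assert abs(t.components[1, 1]) > 0.99

    def test_complete_basis_preserves_variance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((300, 16))
        t = fit_pca(X, d=16)
        err = np.mean((t.back_project(t.project(X)) - X) ** 2)
        assert err < 1e-20

    def test_projection_has_diagonal_covariance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((2000, 12)) @ rng.standard_normal((12, 12))
        L = fit_pca(X, d=6).project(X)
        C = np.cov(L)
        off = np.abs(C - np.diag(np.diag(C))).max()
        assert off < 1e-8 * np.trace(C)

    def test_reconstruction_error_non_increasing_in_d(self, patchset):
        X = patchset.patches[:800]
        errs = []
        for d in (5, 20, 60, 120):
            t = fit_pca(X, d=d)
            errs.append(np.mean((t.back_project(t.project(X)) - X) ** 2))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_d_beyond_pixel_count_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((50, 9)), d=10)


class TestDoGBank:
    def test_kernel_zero_sum_unit_norm(self, lgn_bank):
        assert abs(lgn_bank.kernel.sum()) < 1e-12
        assert np.isclose(np.linalg.norm(lgn_bank.kernel), 1.0)

    def test_constant_patch_silences_both_polarities(self, lgn_bank):
        on, off = dog_filter_patch(np.full((15, 15), 2.0), lgn_bank)
        assert np.max(on) < 1e-10 and np.max(off) < 1e-10

    def test_bright_spot_drives_on_centre_and_off_surround(self, lgn_bank):
        patch = np.zeros((15, 15))
        patch[7, 7] = 1.0
        on, off = dog_filter_patch(patch, lgn_bank)
        assert on[7, 7] > 0
        assert off[7, 3] > 0 or off[3, 7] > 0  # surround ring
        # direct evaluation: response at the centre equals the kernel centre
        kc = lgn_bank.kernel.shape[0] // 2
        assert np.isclose(on[7, 7], lgn_bank.kernel[kc, kc])

    def test_polarities_are_mutually_exclusive_and_antisymmetric(self, lgn_bank, patchset):
        patch = patchset.patches[0].reshape(15, 15)
        on, off = dog_filter_patch(patch, lgn_bank)
        assert np.all((on == 0) | (off == 0))
        on2, off2 = dog_filter_patch(-patch, lgn_bank)
        np.testing.assert_allclose(on2, off, atol=1e-12)
        np.testing.assert_allclose(off2, on, atol=1e-12)


class TestLatencyEncode:
    def test_inverse_response_latencies_and_top_selection(self):
        sl = latency_encode(np.array([4.0, 2.0, 8.0, 1.0]), top_fraction=0.25)
        np.testing.assert_allclose(sl.latencies, [0.25, 0.5, 0.125, 1.0])
        assert list(sl.order) == [2]   # only the strongest (r=8) propagates

    def test_ties_broken_by_afferent_index(self):
        sl = latency_encode(np.ones(10), top_fraction=0.3)
        assert list(sl.order) == [0, 1, 2]

    def test_rank_order_invariant_to_contrast_scaling(self):
        rng = np.random.default_rng(0)
        r = rng.random(50)
        a = latency_encode(r, 0.1)
        b = latency_encode(3.7 * r, 0.1)
        np.testing.assert_array_equal(a.order, b.order)

    def test_silent_input_yields_empty_propagated_set(self):
        sl = latency_encode(np.zeros(20), 0.1)
        assert sl.empty and sl.order.size == 0

    def test_zero_responses_never_propagate(self):
        r = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        sl = latency_encode(r, top_fraction=0.3)
        assert list(sl.order) == [2]

    @pytest.mark.parametrize("frac", [0.0, 1.5, -0.1])
    def test_invalid_fraction(self, frac):
        with pytest.raises(ValueError):
            latency_encode(np.ones(5), frac)


def test_merged_bank_has_one_afferent_per_pixel_split_has_two():
    merged = build_lgn_bank(15, 5.0, mode="merged")
    split = build_lgn_bank(15, 5.0, mode="split")
    assert merged.n_afferents == 225
    assert split.n_afferents == 450
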