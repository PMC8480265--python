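import numpy as np
import pytest

from earlyvis import stats, synthetic
from earlyvis.gabor import GaborParams
from earlyvis.synthetic import (gen_gabor_rf, gen_pink_noise_images,
                                gen_reference_sample, gen_tuned_population,
                                sample_patches, spectral_slope)


class TestPinkNoise:
    def test_white_noise_limit_has_flat_spectrum(self):
        ims = gen_pink_noise_images(6, 20, 5, exponent=0.0, seed=0)
        slopes = [spectral_slope(im, 5.0) for im in ims.images]
        assert abs(np.mean(slopes)) < 0.1

    def test_spectral_slope_tracks_exponent(self):
        slopes = [spectral_slope(gen_pink_noise_images(1, 20, 5, 1.0, seed=s).images[0], 5.0)
                  for s in range(20)]
        assert abs(np.mean(slopes) + 1.0) < 0.1

    def test_zero_mean_unit_variance(self):
        im = gen_pink_noise_images(1, 20, 5, seed=3).images[0]
        assert abs(im.mean()) < 1e-12
        assert abs(im.std() - 1.0) < 1e-12

    def test_deterministic_under_seed(self):
        a = gen_pink_noise_images(3, 20, 5, seed=7)
        b = gen_pink_noise_images(3, 20, 5, seed=7)
        for x, y in zip(a.images, b.images):
            np.testing.assert_array_equal(x, y)

    @pytest.mark.parametrize("kw", [{"n": 0}, {"n": 1, "exponent": -1.0},
                                    {"n": 1, "field_deg": 0.0}])
    def test_invalid_arguments(self, kw):
        with pytest.raises(ValueError):
            gen_pink_noise_images(**{"field_deg": 20, "px_per_deg": 5, **kw})

    def test_structured_surrogate_shares_geometry_and_normalisation(self):
        ims = synthetic.gen_natural_surrogate_images(2, 20, 5, seed=5)
        assert ims.images[0].shape == (100, 100)
        assert abs(ims.images[0].mean()) < 1e-9
        assert abs(ims.images[0].std() - 1.0) < 1e-9


class TestSamplePatches:
    def test_patch_row_length_is_225_at_study_geometry(self, pink_images):
        ps = sample_patches(pink_images, 50, patch_deg=3.0, seed=0)
        assert ps.patches.shape == (50, 225)
        assert ps.patch_px == 15

    def test_constant_image_gives_constant_patches(self):
        ims = synthetic.ImageSet(images=[np.full((40, 40), 3.5)], px_per_deg=5, field_deg=8)
        ps = sample_patches(ims, 10, 3.0, seed=1)
        assert np.all(ps.patches == 3.5)

    def test_same_seed_gives_identical_coordinates(self, pink_images):
        a = sample_patches(pink_images, 100, 3.0, seed=9)
        b = sample_patches(pink_images, 100, 3.0, seed=9)
        np.testing.assert_array_equal(a.source_coords, b.source_coords)
        np.testing.assert_array_equal(a.patches, b.patches)

    def test_coords_inside_images_and_patches_match_source(self, pink_images):
        ps = sample_patches(pink_images, 200, 3.0, seed=2)
        h, w = pink_images.images[0].shape
        assert ps.source_coords[:, 1].max() <= h - 15
        assert ps.source_coords[:, 2].max() <= w - 15
        i, r, c = ps.source_coords[5]
        np.testing.assert_array_equal(
            ps.patches[5], pink_images.images[i][r:r + 15, c:c + 15].ravel())

    def test_patch_larger_than_image_rejected(self):
        ims = synthetic.ImageSet(images=[np.zeros((10, 10))], px_per_deg=5, field_deg=2)
        with pytest.raises(ValueError):
            sample_patches(ims, 5, patch_deg=3.0, seed=0)


class TestGaborRF:
    def test_odd_symmetric_phase_sums_to_zero(self):
        rf = gen_gabor_rf(GaborParams(phase_deg=90.0, theta_deg=0.0), 15, 5.0)
        assert abs(rf.sum()) < 1e-10

    def test_zero_frequency_limit_is_gaussian_blob(self):
        p = GaborParams(freq=1e-9, sigma_x=0.4, sigma_y=0.4, phase_deg=0.0)
        rf = gen_gabor_rf(p, 15, 5.0)
        from earlyvis.gabor import patch_grid
        xx, yy = patch_grid((15, 15), 5.0)
        blob = np.exp(-(xx**2 + yy**2) / (2 * 0.4**2))
        assert np.max(np.abs(rf - blob)) < 1e-6

    def test_noise_deterministic_under_seed(self):
        a = gen_gabor_rf(GaborParams(), 15, 5.0, noise_sd=0.3, seed=4)
        b = gen_gabor_rf(GaborParams(), 15, 5.0, noise_sd=0.3, seed=4)
        np.testing.assert_array_equal(a, b)


class TestReferenceSample:
    def test_tight_central_component_lands_in_square(self):
        ref = gen_reference_sample("fsv", 2000, dist_params={
            "weights": [1.0], "means": [[0.35, 0.35]],
            "covs": [[[0.002, 0.0], [0.0, 0.002]]]}, seed=0)
        inside = np.mean((ref.values[:, 0] < 0.5) & (ref.values[:, 1] < 0.5))
        assert inside >= 0.95

    def test_truncated_to_positive_orthant(self):
        ref = gen_reference_sample("fsv", 500, seed=1)
        assert np.all(ref.values > 0)

    def test_identical_seeds_have_near_zero_kl(self):
        a = gen_reference_sample("bandwidth", 400, seed=2)
        b = gen_reference_sample("bandwidth", 400, seed=2)
        kl = stats.kl_from_samples(a.values[:, 0], b.values[:, 0])
        assert abs(kl) < 1e-9

    def test_degenerate_size_two_still_supports_kde(self):
        ref = gen_reference_sample("bandwidth", 2, seed=3)
        dens = stats.estimate_pdf(ref.values[:, 0])
        assert abs(dens.integral() - 1.0) < 1e-2

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            gen_reference_sample("fsv", 1, seed=0)


class TestTunedPopulation:
    def test_flat_tuning_has_zero_information(self):
        pop = gen_tuned_population(5, base=10.0, amp=0.0, seed=0)
        assert all(pop.closed_form_fi(th) == 0.0 for th in (0.0, 45.0, 133.0))

    def test_closed_form_matches_poisson_formula(self):
        pop = gen_tuned_population(1, base=10.0, amp=8.0, pref_deg=[30.0], seed=0)
        th = 55.0
        d = 2 * np.deg2rad(th - 30.0)
        f = 10 + 8 * np.cos(d)
        fp = -16 * np.sin(d)
        assert np.isclose(pop.closed_form_fi(th), fp**2 / f)

    def test_sampling_deterministic_under_seed(self):
        a = gen_tuned_population(4, seed=5).sample(20.0, 10)
        b = gen_tuned_population(4, seed=5).sample(20.0, 10)
        np.testing.assert_array_equal(a, b)

    def test_poisson_requires_positive_rates(self):
        with pytest.raises(ValueError):
            gen_tuned_population(2, base=5.0, amp=6.0)
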