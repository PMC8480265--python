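import numpy as np
import pytest

from earlyvis import synthetic
from earlyvis.gabor import GaborParams
from earlyvis.probing import (_halfwidth, cos2_orientation_responder,
                              estimate_fi, estimate_otc,
                              fisher_information, linear_decode,
                              linear_rectified_responder, make_swg,
                              population_responses, ResponseMatrix)
from earlyvis.synthetic import gen_gabor_rf, gen_tuned_population




class TestSWG:
    def test_noiseless_is_exact_sinusoid(self):
        g = make_swg(30.0, 1.0, 45.0, np.inf, 15, 5.0)
        x = (np.arange(15) - 7) / 5.0
        xx, yy = np.meshgrid(x, x)
        c = xx * np.cos(np.deg2rad(30)) + yy * np.sin(np.deg2rad(30))
        np.testing.assert_allclose(g, np.sqrt(2) * np.sin(2 * np.pi * c + np.pi / 4))

    def test_zero_db_noise_matches_signal_power(self):
        vars_ = []
        for s in range(100):
            g = make_swg(0.0, 1.25, 0.0, 0.0, 15, 5.0, seed=s)
            clean = make_swg(0.0, 1.25, 0.0, np.inf, 15, 5.0)
            vars_.append(np.var(g - clean))
        assert abs(np.mean(vars_) - 1.0) < 0.05

    def test_axial_symmetry_up_to_phase(self):
        a = make_swg(40.0, 1.0, 30.0, np.inf, 15, 5.0)
        b = make_swg(220.0, 1.0, -30.0, np.inf, 15, 5.0)
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_super_nyquist_rejected(self):
        with pytest.raises(ValueError):
            make_swg(0.0, 3.0, 0.0, np.inf, 15, 5.0)

    def test_deterministic_under_seed(self):
        np.testing.assert_array_equal(make_swg(10, 1, 0, 0, seed=3),
                                      make_swg(10, 1, 0, 0, seed=3))


class TestOTC:
    def test_cos2_responder_bandwidth_is_45_degrees(self):
        responder = cos2_orientation_responder(theta0_deg=77.0)
        otc = estimate_otc(responder, 1.25, snr_db=np.inf, reps=1, n_boot=0, seed=0)
        assert otc.bandwidth_deg == pytest.approx(45.0, abs=1.0)

    def test_halfwidth_of_analytic_cos2_curve(self):
        orients = np.arange(0.0, 180.0, 2.0)
        curve = np.cos(np.deg2rad(orients - 33.0)) ** 2
        assert _halfwidth(orients, curve) == pytest.approx(45.0, abs=1.0)

    def test_isotropic_blob_has_flat_curve(self):
        blob = gen_gabor_rf(GaborParams(freq=1e-9, sigma_x=0.4, sigma_y=0.4,
                                        phase_deg=0.0), 15, 5.0)
        rect = linear_rectified_responder(blob[None])
        otc = estimate_otc(lambda p: rect(p)[0], 1.25, snr_db=np.inf, reps=1,
                           n_boot=0, seed=0)
        assert otc.flat

    def test_elongation_sharpens_tuning(self):
        bws = []
        for sy in (0.3, 0.9):
            rf = gen_gabor_rf(GaborParams(theta_deg=0.0, freq=1.25, sigma_x=0.3,
                                          sigma_y=sy), 15, 5.0)
            rect = linear_rectified_responder(rf[None])
            otc = estimate_otc(lambda p: rect(p)[0], 1.25, snr_db=np.inf,
                               reps=1, n_boot=0, seed=0)
            bws.append(otc.bandwidth_deg)
        assert bws[1] < bws[0]

    def test_bootstrap_ci_covers_estimate(self):
        rf = gen_gabor_rf(GaborParams(theta_deg=45.0, freq=1.25, sigma_x=0.3,
                                      sigma_y=0.5), 15, 5.0)
        rect = linear_rectified_responder(rf[None])
        otc = estimate_otc(lambda p: rect(p)[0], 1.25, snr_db=0.0, reps=10,
                           orient_step_deg=6.0, phase_step_deg=30.0,
                           n_boot=100, seed=1)
        lo, hi = otc.ci95
        assert lo <= otc.bandwidth_deg <= hi


class TestFisherInformation:
    def test_untuned_population_carries_no_information(self):
        pop = gen_tuned_population(4, base=10.0, amp=0.0, seed=0)
        orients = np.arange(0.0, 180.0, 4.0)
        resp = np.stack([pop.sample(o, 400).T for o in orients], axis=1)
        J, _ = fisher_information(resp, orients)
        true_scale = 16.0  # magnitude of a tuned unit's FI for reference
        assert np.mean(J) < 0.1 * true_scale

    def test_matches_closed_form_poisson_within_15_percent(self):
        pop = gen_tuned_population(6, base=10.0, amp=8.0, seed=1)
        orients = np.arange(0.0, 180.0, 4.0)
        resp = np.stack([pop.sample(o, 1000).T for o in orients], axis=1)
        J, _ = fisher_information(resp, orients)
        true = np.mean([pop.closed_form_fi(o) for o in orients])
        assert abs(J.mean() - true) / true < 0.15

    def test_additive_over_independent_unit_copies(self):
        pop = gen_tuned_population(3, base=12.0, amp=6.0, seed=2)
        orients = np.arange(0.0, 180.0, 4.0)
        resp = np.stack([pop.sample(o, 300).T for o in orients], axis=1)
        J1, _ = fisher_information(resp, orients)
        J2, _ = fisher_information(np.concatenate([resp, resp]), orients)
        np.testing.assert_allclose(J2, 2 * J1, rtol=1e-9)

    def test_stable_under_halved_repetitions(self):
        pop = gen_tuned_population(4, base=10.0, amp=8.0, seed=3)
        orients = np.arange(0.0, 180.0, 4.0)
        resp = np.stack([pop.sample(o, 800).T for o in orients], axis=1)
        J_full, jack = fisher_information(resp, orients)
        J_half, _ = fisher_information(resp[:, :, :400], orients)
        R = jack.size
        se = np.sqrt((R - 1) / R * np.sum((jack - jack.mean()) ** 2))
        assert abs(J_half.mean() - J_full.mean()) <= max(4 * 1.96 * se,
                                                         0.15 * J_full.mean())

    def test_estimate_fi_from_response_matrix(self):
        pop = gen_tuned_population(4, base=10.0, amp=8.0, seed=4)
        orients = np.arange(0.0, 180.0, 4.0)
        reps = 200
        resp = np.stack([pop.sample(o, reps).T for o in orients], axis=1)
        rm = ResponseMatrix(
            responses=resp.transpose(0, 2, 1).reshape(4, -1),
            labels_deg=np.tile(orients, reps))
        est = estimate_fi(rm)
        true = np.mean([pop.closed_form_fi(o) for o in orients])
        assert est.ci95[0] < est.mean_J < est.ci95[1]
        assert abs(est.mean_J - true) / true < 0.3


class TestLinearDecode:
    @staticmethod
    def tuned_population_matrix(noise_sd, seed=0, reps=12):
        pop = gen_tuned_population(20, base=10.0, amp=8.0, noise="gaussian",
                                   gaussian_sd=noise_sd, seed=seed)
        orients = np.arange(0.0, 180.0, 4.0)
        resp = np.concatenate([pop.sample(o, reps) for o in orients], axis=0).T
        return ResponseMatrix(responses=resp,
                              labels_deg=np.repeat(orients, reps))

    def test_separable_clusters_decode_perfectly(self):
        # well-separated full-rank Gaussian clusters, one per orientation class
        rng = np.random.default_rng(0)
        orients = np.arange(0.0, 180.0, 4.0)
        centres = rng.normal(0, 10.0, (orients.size, 20))
        reps = 9
        resp = np.concatenate([c + rng.normal(0, 0.1, (reps, 20))
                               for c in centres], axis=0).T
        rm = ResponseMatrix(responses=resp, labels_deg=np.repeat(orients, reps))
        res = linear_decode(rm, folds=3, reps=3, seed=0)
        assert res.accuracy > 0.99

    def test_shuffled_labels_fall_to_chance(self):
        rm = self.tuned_population_matrix(noise_sd=1.0)
        rng = np.random.default_rng(1)
        rm.labels_deg = rng.permutation(rm.labels_deg)
        res = linear_decode(rm, folds=3, reps=5, seed=1)
        assert abs(res.accuracy - res.chance) < 3 * res.chance

    def test_accuracy_monotone_in_noise_level(self):
        accs = [linear_decode(self.tuned_population_matrix(sd, seed=2),
                              folds=3, reps=3, seed=2).accuracy
                for sd in (0.5, 4.0, 16.0)]
        assert accs[0] >= accs[1] >= accs[2]

    def test_too_few_trials_per_class_rejected(self):
        rm = self.tuned_population_matrix(noise_sd=1.0, reps=3)
        with pytest.raises(ValueError):
            linear_decode(rm, folds=5, reps=2)


def test_population_responses_shape_and_determinism():
    rf = gen_gabor_rf(GaborParams(theta_deg=0.0, freq=1.25, sigma_x=0.3,
                                  sigma_y=0.5), 15, 5.0)
    rect = linear_rectified_responder(rf[None])
    rm1 = population_responses(rect, np.arange(0, 180, 20.0), reps=3, seed=5)
    rm2 = population_responses(rect, np.arange(0, 180, 20.0), reps=3, seed=5)
    assert rm1.responses.shape == (1, 27)
    np.testing.assert_array_equal(rm1.responses, rm2.responses)
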