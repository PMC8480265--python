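import numpy as np
import pytest

from earlyvis.frontend import SpikeList, build_lgn_bank, encode_patch
from earlyvis.stdp import (STDPNet, STDPRule, ThresholdMisconfiguration,
                           default_threshold, init_net, integrate,
                           respond_spikelist, stdp_recover_rfs, stdp_respond,
                           stdp_train, step_wta)
from conftest import make_bar_patches


def spikes_from_order(order, n_afferents):
    lat = np.full(n_afferents, np.inf)
    lat[list(order)] = np.arange(1, len(order) + 1, dtype=float)
    return SpikeList(latencies=lat, order=np.asarray(order), n_afferents=n_afferents)


class TestIntegrate:
    def test_unit_weights_fire_at_third_spike(self):
        net = STDPNet(weights=np.ones((1, 10)), theta=3.0)
        fired, rank, u = integrate(net, spikes_from_order([4, 2, 7, 9], 10), 0)
        assert fired and rank == 3 and u == 3.0

    def test_subthreshold_returns_total_drive(self):
        net = STDPNet(weights=np.full((1, 10), 0.5), theta=10.0)
        fired, rank, u = integrate(net, spikes_from_order([0, 1, 2], 10), 0)
        assert not fired and rank is None and np.isclose(u, 1.5)

    def test_scale_invariance_of_fire_rank(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.1, 1.0, (1, 30))
        sl = spikes_from_order(list(range(0, 30, 3)), 30)
        _, r1, _ = integrate(STDPNet(weights=w, theta=2.0), sl, 0)
        _, r2, _ = integrate(STDPNet(weights=2 * w, theta=4.0), sl, 0)
        assert r1 == r2


class TestRule:
    def test_ltp_ltd_magnitudes_at_half_weight(self):
        rule = STDPRule()
        assert np.isclose(rule.delta_ltp(np.array([0.5]))[0], 3.19e-3, atol=5e-6)
        assert np.isclose(rule.delta_ltd(np.array([0.5]))[0], -3.62e-3, atol=5e-6)

    def test_updates_vanish_at_bounds(self):
        rule = STDPRule()
        assert rule.delta_ltp(np.array([1.0]))[0] == 0.0
        assert rule.delta_ltd(np.array([0.0]))[0] == 0.0

    def test_depression_never_crosses_lower_bound(self):
        rule = STDPRule()
        w = np.array([1e-8])
        assert w + rule.delta_ltd(w) > 0.0


class TestStepWTA:
    def test_winner_updates_match_rule_others_unchanged(self):
        w = np.full((2, 8), 0.5)
        w[1] *= 0.2  # neuron 0 wins (fires earlier)
        net = STDPNet(weights=w.copy(), theta=1.4, polarity=None)
        sl = spikes_from_order([0, 1, 2, 3], 8)
        winner = step_wta(net, sl)
        assert winner == 0
        rule = net.rule
        # neuron 0 crossed at the 3rd spike: afferents 0,1,2 causal, rest LTD
        np.testing.assert_allclose(net.weights[0, [0, 1, 2]],
                                   0.5 + rule.delta_ltp(np.array([0.5]))[0])
        np.testing.assert_allclose(net.weights[0, 3:],
                                   0.5 + rule.delta_ltd(np.array([0.5]))[0])
        np.testing.assert_array_equal(net.weights[1], w[1])

    def test_tie_goes_to_lowest_id(self):
        net = STDPNet(weights=np.ones((3, 6)), theta=2.0, polarity=None)
        assert step_wta(net, spikes_from_order([0, 1, 2], 6), learn=False) == 0

    def test_no_fire_no_update(self):
        w = np.full((2, 6), 0.1)
        net = STDPNet(weights=w.copy(), theta=5.0, polarity=None)
        assert step_wta(net, spikes_from_order([0, 1], 6)) is None
        np.testing.assert_array_equal(net.weights, w)


class TestTraining:
    def test_converged_weights_bimodal_on_oriented_bars(self, lgn_bank):
        patches = make_bar_patches(3000, seed=0)
        net = init_net(n_neurons=4, n_afferents=lgn_bank.n_afferents, seed=1)
        log = stdp_train(net, patches, lgn_bank)
        near_bound = ((net.weights < 0.05) | (net.weights > 0.95)).mean(axis=1)
        assert np.all(near_bound >= 0.7)
        assert log["winner_histogram"].sum() + log["n_skipped"] == 3000

    def test_weight_change_stabilises(self, trained_stdp):
        _, log = trained_stdp
        dw = log["mean_abs_dw_per_block"]
        assert dw[-1] < 0.2 * dw[0]

    def test_weights_strictly_inside_bounds(self, trained_stdp):
        net, _ = trained_stdp
        assert net.weights.min() > 0.0 and net.weights.max() < 1.0

    def test_training_bit_reproducible(self, lgn_bank):
        patches = make_bar_patches(500, seed=3)
        nets = []
        for _ in range(2):
            net = init_net(n_neurons=4, n_afferents=lgn_bank.n_afferents, seed=9)
            stdp_train(net, patches, lgn_bank)
            nets.append(net.weights)
        np.testing.assert_array_equal(nets[0], nets[1])

    def test_unreachable_threshold_raises(self, lgn_bank):
        patches = make_bar_patches(1200, seed=4)
        net = init_net(n_neurons=4, n_afferents=lgn_bank.n_afferents,
                       theta=1e6, seed=2)
        with pytest.raises(ThresholdMisconfiguration):
            stdp_train(net, patches, lgn_bank)


class TestRFRecovery:
    def test_one_hot_weight_reproduces_kernel(self):
        bank = build_lgn_bank(15, 5.0, mode="split")
        w = np.zeros((1, bank.n_afferents))
        w[0, 112] = 1.0  # ON afferent at pixel (7, 7)
        net = STDPNet(weights=w, theta=1.0, polarity=None)
        rf = stdp_recover_rfs(net, bank)[0]
        kc = bank.kernel.shape[0] // 2
        expect = bank.kernel[kc - 7:kc + 8, kc - 7:kc + 8]
        np.testing.assert_allclose(rf, expect, atol=1e-12)

    def test_uniform_weights_cancel_by_on_off_symmetry(self):
        bank = build_lgn_bank(15, 5.0, mode="split")
        net = STDPNet(weights=np.full((1, bank.n_afferents), 0.4), theta=1.0,
                      polarity=None)
        rf = stdp_recover_rfs(net, bank)[0]
        assert np.max(np.abs(rf)) < 1e-10 * np.linalg.norm(bank.kernel)

    def test_linearity_in_weights(self):
        bank = build_lgn_bank(15, 5.0, mode="split")
        rng = np.random.default_rng(5)
        w1, w2 = rng.random((2, 1, bank.n_afferents))
        rf = lambda w: stdp_recover_rfs(STDPNet(weights=w, theta=1, polarity=None), bank)[0]
        np.testing.assert_allclose(rf(w1 + w2), rf(w1) + rf(w2), atol=1e-10)


class TestRespond:
    def test_vanishing_threshold_fires_everything(self, trained_stdp, lgn_bank, patchset):
        net, _ = trained_stdp
        patch = patchset.patches[0]
        r = stdp_respond(net, patch, lgn_bank, threshold_scale=-1.0 + 1e-9)
        sl = encode_patch(patch, lgn_bank)
        driven = net.weights[:, sl.order].sum(axis=1) > 0
        np.testing.assert_array_equal(r.astype(bool), driven)

    def test_huge_threshold_silences_everything(self, trained_stdp, lgn_bank, patchset):
        net, _ = trained_stdp
        r = stdp_respond(net, patchset.patches[1], lgn_bank, threshold_scale=1e9)
        assert np.all(r == 0)

    def test_population_spike_count_monotone_in_threshold(self, trained_stdp,
                                                          lgn_bank, patchset):
        net, _ = trained_stdp
        counts = []
        for s in (-0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75):
            tot = sum(stdp_respond(net, p, lgn_bank, threshold_scale=s).sum()
                      for p in patchset.patches[:40])
            counts.append(tot)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_spike_mode_equals_thresholded_potential(self, trained_stdp, lgn_bank,
                                                     patchset):
        net, _ = trained_stdp
        for p in patchset.patches[:10]:
            sl = encode_patch(p, lgn_bank)
            u = respond_spikelist(net, sl, mode="potential")
            s = respond_spikelist(net, sl, threshold_scale=0.3, mode="spike")
            np.testing.assert_array_equal(s, (u >= net.theta * 1.3).astype(float))


def test_default_threshold_calibration():
    # untrained mean weight 1/2 over ceil(0.1 * 225) = 23 propagated spikes
    assert np.isclose(default_threshold(225), 0.6 * 0.5 * 23)
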