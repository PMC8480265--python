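"""Rank-order STDP network of integrate-and-fire V1 neurons.

Each patch is converted by the LGN front end into a rank-ordered list of
first-spike latencies, of which only the earliest fraction propagates.  A
V1 neuron accumulates its afferent weights in spike order and fires when the
running potential crosses the threshold (the Heaviside gate then stops
further integration).  During learning a winner-take-all rule lets only the
earliest-firing neuron update its weights, with the soft-bound
multiplicative rule

    LTP (afferent spike at or before the postsynaptic spike):
        dw = +alpha_plus  * (w_max - w)^mu_plus
    LTD (all other afferents; the depression window is unbounded):
        dw = -alpha_minus * (w - w_min)^mu_minus

so weights approach but never reach the bounds (0, 1).  After training the
inhibition is switched off, every neuron integrates independently, and the
threshold may be rescaled to probe how overall excitability shapes the
information content of the population code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .frontend import LGNBank, SpikeList, encode_patch
from .synthetic import PatchSet


class ThresholdMisconfiguration(RuntimeError):
    """No neuron fired for an entire window of patches during training."""


@dataclass
class STDPRule:
    """Soft-bound multiplicative rank-based STDP rule.

    The windowing function is rank-based: K = 1 for every propagated spike
    (LTP side limited to spikes up to the postsynaptic spike), and the
    depression window is effectively infinite, so every non-causal afferent
    is depressed on each update.

    Because the update is a discrete step of a continuous soft-bound rule,
    a raw depression step could overshoot w_min for weights already very
    close to it (the continuous dynamics cannot cross the bound).  The step
    is therefore capped at half the remaining distance to the bound, which
    keeps weights strictly inside (w_min, w_max) without altering the update
    anywhere it matters (the cap only engages within ~3e-3 of the bound).
    """

    alpha_plus: float = 5e-3
    alpha_minus: float = 0.75 * 5e-3
    mu_plus: float = 0.65
    mu_minus: float = 0.05
    w_min: float = 0.0
    w_max: float = 1.0
    bound_guard: float = 0.5

    def delta_ltp(self, w: np.ndarray) -> np.ndarray:
        gap = self.w_max - w
        return np.minimum(self.alpha_plus * gap ** self.mu_plus,
                          self.bound_guard * gap)

    def delta_ltd(self, w: np.ndarray) -> np.ndarray:
        gap = w - self.w_min
        return -np.minimum(self.alpha_minus * gap ** self.mu_minus,
                           self.bound_guard * gap)


def default_threshold(n_afferents: int, top_fraction: float = 0.1,
                      fraction_of_drive: float = 0.6) -> float:
    """Training threshold calibrated to the untrained network.

    An untrained neuron has mean weight 1/2, so the expected total drive
    from the ceil(top_fraction * n) propagated spikes is n_prop / 2; the
    threshold is set at ``fraction_of_drive`` of that, making an untrained
    neuron cross after roughly 60% of the propagated spikes.
    """
    n_prop = int(np.ceil(top_fraction * n_afferents))
    return fraction_of_drive * 0.5 * n_prop


@dataclass
class STDPNet:
    """Winner-take-all population of integrate-and-fire neurons."""

    weights: np.ndarray                 # (n_neurons, n_afferents), in (0, 1)
    theta: float
    rule: STDPRule = field(default_factory=STDPRule)
    inhibition: Literal["wta", "off"] = "wta"
    seed: int | None = None
    polarity: np.ndarray | None = None  # (n_neurons, n_afferents) signed drive tally

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def n_afferents(self) -> int:
        return self.weights.shape[1]

    @property
    def n_weights(self) -> int:
        return self.weights.size


def init_net(n_neurons: int = 225, n_afferents: int = 225,
             theta: float | None = None, rule: STDPRule | None = None,
             seed: int | None = 0, top_fraction: float = 0.1) -> STDPNet:
    """Fresh network with i.i.d. uniform(0,1) weights and calibrated threshold."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.0, 1.0, size=(n_neurons, n_afferents))
    if theta is None:
        theta = default_threshold(n_afferents, top_fraction)
    return STDPNet(weights=w, theta=theta, rule=rule or STDPRule(), seed=seed,
                   polarity=np.zeros((n_neurons, n_afferents)))


def _fire_ranks(weights: np.ndarray, order: np.ndarray, theta: float):
    """Vectorised threshold crossing for all neurons.

    Returns (fire_rank per neuron; 0 = never fires, else 1-based index into
    ``order``) and the final potential (sum up to crossing, or total drive).
    """
    drive = weights[:, order]                  # (n_neurons, n_spikes)
    u = np.cumsum(drive, axis=1)
    crossed = u >= theta
    any_fire = crossed.any(axis=1)
    rank = np.where(any_fire, crossed.argmax(axis=1) + 1, 0)
    u_final = np.where(any_fire, u[np.arange(u.shape[0]), np.maximum(rank - 1, 0)],
                       u[:, -1] if u.shape[1] else 0.0)
    return rank, u_final


def integrate(net: STDPNet, spikes: SpikeList, neuron: int):
    """Integrate one neuron over the propagated spikes in latency order.

    Returns (fired, fire_rank | None, u_final): the potential accumulates
    the afferent weight at each propagated spike and integration stops at
    the first crossing of theta.
    """
    if spikes.empty:
        return False, None, 0.0
    rank, u_final = _fire_ranks(net.weights[neuron:neuron + 1], spikes.order, net.theta)
    fired = rank[0] > 0
    return bool(fired), (int(rank[0]) if fired else None), float(u_final[0])


def step_wta(net: STDPNet, spikes: SpikeList, learn: bool = True):
    """One winner-take-all learning step on a single spike list.

    The winner is the neuron with the earliest threshold crossing (ties
    broken by lowest id).  Its afferents with propagated spikes arriving at
    or before the crossing get LTP; every other afferent (later spikes and
    silent afferents alike) gets LTD.  Non-winners are unchanged.  Returns
    the winner id or None when no neuron fires.
    """
    if spikes.empty:
        return None
    ranks, _ = _fire_ranks(net.weights, spikes.order, net.theta)
    fired = ranks > 0
    if not fired.any():
        return None
    ranks_f = np.where(fired, ranks, np.iinfo(np.int64).max)
    winner = int(np.argmin(ranks_f))           # argmin takes the lowest id on ties
    if not learn:
        return winner
    k = ranks[winner]                          # crossing index (1-based)
    causal = spikes.order[:k]
    w = net.weights[winner]
    dw = net.rule.delta_ltd(w)                 # default: depress everything
    dw[causal] = net.rule.delta_ltp(w[causal])
    # the continuous soft-bound rule keeps w in the open interval; float
    # rounding of vanishing gaps needs an explicit guard
    tiny = 1e-12 * (net.rule.w_max - net.rule.w_min)
    net.weights[winner] = np.clip(w + dw, net.rule.w_min + tiny,
                                  net.rule.w_max - tiny)
    if net.polarity is not None and spikes.signed_map is not None:
        signed = spikes.signed_map.ravel()
        if signed.size == net.n_afferents:     # merged-polarity bank
            net.polarity[winner, causal] += signed[causal]
    return winner


def stdp_train(
    net: STDPNet,
    patches: PatchSet | np.ndarray,
    bank: LGNBank,
    top_fraction: float = 0.1,
    skip_window: int = 1000,
    log_block: int = 1000,
) -> dict:
    """Train the network on a patch stream (one WTA step per patch, in order).

    Returns a log with the winner histogram, skip count and the mean |dw|
    trajectory per block.  Raises ``ThresholdMisconfiguration`` if every
    patch in a ``skip_window`` stretch fails to elicit a spike.
    """
    X = patches.patches if isinstance(patches, PatchSet) else np.asarray(patches)
    if bank.n_afferents != net.n_afferents:
        raise ValueError("LGN bank afferent count does not match network")
    winners = np.zeros(net.n_neurons, dtype=int)
    skips = 0
    run_skips = 0
    mean_dw = []
    w_prev = net.weights.copy()
    for j in range(X.shape[0]):
        sl = encode_patch(X[j], bank, top_fraction)
        winner = step_wta(net, sl)
        if winner is None:
            skips += 1
            run_skips += 1
            if run_skips >= skip_window:
                raise ThresholdMisconfiguration(
                    f"no neuron fired for {skip_window} consecutive patches "
                    f"(theta={net.theta}); lower the threshold")
        else:
            winners[winner] += 1
            run_skips = 0
        if (j + 1) % log_block == 0:
            mean_dw.append(float(np.mean(np.abs(net.weights - w_prev))))
            w_prev = net.weights.copy()
    return {"winner_histogram": winners, "n_skipped": skips,
            "mean_abs_dw_per_block": mean_dw, "block": log_block,
            "n_patches": int(X.shape[0])}


def stdp_recover_rfs(net: STDPNet, bank: LGNBank) -> np.ndarray:
    """Retinal RFs xi = sum_i w_i psi_i as (n_neurons, px, px) maps.

    Split-polarity banks subtract the OFF-kernel contribution; merged banks
    use the per-(neuron, afferent) dominant polarity accumulated during
    training to sign each kernel.
    """
    maps = np.empty((net.n_neurons, bank.patch_px, bank.patch_px))
    for n in range(net.n_neurons):
        if bank.mode == "merged":
            pol = net.polarity[n] if net.polarity is not None else np.ones(net.n_afferents)
            signs = np.where(pol >= 0, 1.0, -1.0)
            maps[n] = bank.reconstruct_rf(net.weights[n], signs=signs)
        else:
            maps[n] = bank.reconstruct_rf(net.weights[n])
    return maps


def stdp_respond(
    net: STDPNet,
    patch: np.ndarray,
    bank: LGNBank,
    threshold_scale: float = 0.0,
    mode: Literal["spike", "potential"] = "spike",
    top_fraction: float = 0.1,
) -> np.ndarray:
    """Post-training response of every neuron to one patch.

    Inhibition is off: each neuron integrates independently against
    theta_testing = theta_training * (1 + threshold_scale).  ``spike`` mode
    returns binary fired flags; ``potential`` returns the final potential
    with the threshold gate disabled (full propagated drive).
    """
    sl = encode_patch(patch, bank, top_fraction)
    return respond_spikelist(net, sl, threshold_scale, mode)


def respond_spikelist(net: STDPNet, sl: SpikeList, threshold_scale: float = 0.0,
                      mode: Literal["spike", "potential"] = "spike") -> np.ndarray:
    if sl.empty:
        return np.zeros(net.n_neurons)
    if mode == "potential":
        return net.weights[:, sl.order].sum(axis=1)
    theta = net.theta * (1.0 + threshold_scale)
    if theta <= 0:
        return (net.weights[:, sl.order].sum(axis=1) > 0).astype(float)
    ranks, _ = _fire_ranks(net.weights, sl.order, theta)
    return (ranks > 0).astype(float)
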