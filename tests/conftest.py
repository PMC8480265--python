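import numpy as np
import pytest

from earlyvis import frontend, stdp, synthetic


@pytest.fixture(scope="session")
def pink_images():
    return synthetic.gen_pink_noise_images(8, field_deg=20, px_per_deg=5,
                                           exponent=1.0, seed=11)


@pytest.fixture(scope="session")
def structured_images():
    return synthetic.gen_natural_surrogate_images(10, field_deg=20, px_per_deg=5,
                                                  seed=12)


@pytest.fixture(scope="session")
def patchset(structured_images):
    return synthetic.sample_patches(structured_images, 4000, patch_deg=3.0, seed=13)


@pytest.fixture(scope="session")
def lgn_bank():
    return frontend.build_lgn_bank(patch_px=15, px_per_deg=5.0, mode="merged")


def make_bar_patches(n, k=15, px_per_deg=5.0, orientations=(0.0, 90.0), seed=0):
    """Sinusoidal oriented-bar patches at a few fixed orientations."""
    rng = np.random.default_rng(seed)
    x = (np.arange(k) - (k - 1) / 2) / px_per_deg
    xx, yy = np.meshgrid(x, x)
    out = np.empty((n, k * k))
    for j in range(n):
        th = np.deg2rad(rng.choice(orientations))
        ph = rng.uniform(0, 2 * np.pi)
        out[j] = np.sin(2 * np.pi * 1.0 * (xx * np.cos(th) + yy * np.sin(th)) + ph).ravel()
    return out


@pytest.fixture(scope="session")
def trained_stdp(lgn_bank, structured_images):
    """Small STDP net trained on naturalistic surrogate patches."""
    ps = synthetic.sample_patches(structured_images, 6000, patch_deg=3.0, seed=21)
    net = stdp.init_net(n_neurons=30, n_afferents=lgn_bank.n_afferents, seed=22)
    log = stdp.stdp_train(net, ps, lgn_bank)
    return net, log
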