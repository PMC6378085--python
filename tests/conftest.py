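import numpy as np
import pytest

import isvseg as iv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_overfit_patches(seed: int = 7):
    """Eight 64x64 single-pair patches from small phantom frames: the
    memorization fixture (normal morphology, foreground-only labels)."""
    cfg = iv.PhantomConfig(image_size=(64, 112), n_isv_pairs=2,
                           p_abnormal=0.0, seed=seed)
    samples, _ = iv.generate_dataset(5, cfg)
    patches = []
    for i, s in enumerate(samples):
        patches.extend(iv.build_patches(
            s.image, (s.fg_mask | s.bg_mask), side=64, min_h=64, max_h=64,
            augment=False, source_id=i, label_mask=s.fg_mask))
    return iv.patches_to_arrays(patches[:8])


@pytest.fixture(scope="session")
def overfit_patches():
    return make_overfit_patches()


@pytest.fixture
def tiny_network():
    """Smallest trainable dual network, deterministically initialized."""
    net = iv.build_network(iv.NetworkConfig(base_channels=2))
    iv.init_weights(net, seed=0)
    return net
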