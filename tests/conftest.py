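import numpy as np
import pytest

from hdmod.codec import CodeConfig, make_codebooks
from hdmod.ncc import NccConfig, NccEncoder
from hdmod.synth import SyntheticConfig, generate_features


@pytest.fixture(scope="session")
def small_code():
    """A small worked-example-sized code: D=64, N=8, V=1."""
    config = CodeConfig(dim=64, im_size=8, n_superposed=1, seed=1)
    im, perms, tie = make_codebooks(config, identity_permutations=True)
    return config, im, perms, tie


@pytest.fixture(scope="session")
def medium_code():
    """A multi-block code small enough for exhaustive checks: D=64, N=8, V=3."""
    config = CodeConfig(dim=64, im_size=8, n_superposed=3, seed=2)
    im, perms, tie = make_codebooks(config)
    return config, im, perms, tie


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Train/test synthetic gesture streams sharing templates, distinct noise."""
    config = SyntheticConfig(seed=11)
    train = generate_features(config, noise_seed=111)
    test = generate_features(config, noise_seed=211)
    return config, train, test


@pytest.fixture(scope="session")
def ncc_model(synthetic_dataset):
    """Encoder + prototypes trained at a mid-size dimension (D=2048)."""
    from hdmod.ncc import train_prototypes

    config, (train_f, train_l), (test_f, test_l) = synthetic_dataset
    enc = NccEncoder(NccConfig(dim=2048, seed=11))
    grams, glabels = enc.encode_trials(train_f, train_l, config.frames_per_trial)
    protos = train_prototypes(grams, glabels, enc.tie_breaker)
    test_grams, test_glabels = enc.encode_trials(test_f, test_l, config.frames_per_trial)
    return enc, protos, test_grams, test_glabels
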