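import numpy as np
import pytest

from ecnnsvm import PipelineConfig, SynthSpec, generate
from ecnnsvm.network import ECNNConfig


@pytest.fixture(scope="session")
def mini_dataset():
    """Small, strongly-separable four-source study for pipeline-level tests."""
    spec = SynthSpec(n_samples=40, dims=(60, 60, 60, 60),
                     n_informative=(5, 5, 5, 5), effect_size=3.0,
                     minority_fraction=0.3, seed=11)
    return generate(spec)


@pytest.fixture()
def mini_config():
    """Pipeline configuration scaled for unit-test speed."""
    net = ECNNConfig(conv1_filters=16, conv2_filters=8, se_ratio=4,
                     fc_hidden=8, max_epochs=12, patience=4, batch_size=8)
    return PipelineConfig(top_k=6, n_trees=60, ecnn=net, seed=3)


@pytest.fixture()
def tiny_net_config():
    """A network small enough for finite-difference gradient audits."""
    return ECNNConfig(conv1_filters=6, conv2_filters=4, se_ratio=2,
                      fc_hidden=3, dropout1_rate=0.0, dropout2_rate=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
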