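import numpy as np
import pytest

from mvconn.encoder import EncoderSpec
from mvconn.evaluation import ExperimentConfig
from mvconn.network import FusionSpec, TrainConfig
from mvconn.prototypes import LossConfig
from mvconn.synth import SynthConfig, generate_multiview


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_synth():
    """Small, easily separable 3-view dataset with planted truth."""
    cfg = SynthConfig(N=60, region_counts=(6, 5, 4), s=3, effect=5.0, seed=0)
    return generate_multiview(cfg)


@pytest.fixture(scope="session")
def fast_experiment_config():
    """Test-scale experiment: tiny widths, few epochs, seconds per CV run."""
    return ExperimentConfig(
        lam=0.5,
        encoder=EncoderSpec((6, 4), pretrain=True, pretrain_epochs=5),
        fusion=FusionSpec(mode="fuse", position=2, K=4),
        loss=LossConfig(),
        train=TrainConfig(batch_size=16, learning_rate=1e-2, epochs=15, seed=0),
        seed=0,
    )
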