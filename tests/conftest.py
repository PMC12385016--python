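import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from gradiomics.backbone import TrainingConfig, build_test_backbone, train_backbone
from gradiomics.imaging import resize
from gradiomics.saliency import SaliencyResult, mask_qc
from gradiomics.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """24 synthetic images at side 64 under the default study conditions."""
    cfg = SyntheticConfig(n_images=24, seed=5)
    return [resize(s, 64) for s in generate_dataset(cfg)]


@pytest.fixture(scope="session")
def small_net():
    """Untrained seeded backbone (deterministic random weights)."""
    return build_test_backbone(seed=3, side=64, conv_channels=(4, 8, 16))


@pytest.fixture(scope="session")
def trained_net(small_dataset):
    """Backbone briefly trained on the small dataset (for integration tests)."""
    net = build_test_backbone(seed=3, side=64, conv_channels=(4, 8, 16))
    x = np.stack([s.pixels for s in small_dataset])
    y = np.array([s.label for s in small_dataset])
    train_backbone(net, x[:18], y[:18], x[18:], y[18:],
                   TrainingConfig(epochs=3, learning_rate=1e-2, seed=3))
    return net


def central_saliency(shape, margin=0.25):
    """A reliable SaliencyResult whose mask is a centered solid block."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    mask[int(h * margin) : int(h * (1 - margin)), int(w * margin) : int(w * (1 - margin))] = True
    return SaliencyResult(heatmap=mask.astype(float), mask=mask, qc=mask_qc(mask))


@pytest.fixture
def reliable_saliency():
    return central_saliency
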