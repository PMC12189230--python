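import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small bimodal dataset shared by training-level tests (16x16, S=2)."""
    from modnet import SyntheticSpec, generate_dataset
    spec = SyntheticSpec(n_groups=18, height=16, width=16, n_slices=2,
                         seed=3, effect_size=1.0)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    from modnet import ModelConfig
    return ModelConfig(stem_width=4, stage_channels=(4, 4, 8, 8),
                       fusion_width=8, reduction=2, spatial_kernel=3,
                       multiscale_groups=2, n_classes=3)
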