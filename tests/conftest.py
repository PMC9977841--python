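import numpy as np
import pytest

from tsgeo.featurize import FeaturizerConfig
from tsgeo.model import ModelConfig, PSIModel
from tsgeo.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A few toy reactions with reference TSs and property labels."""
    return generate(SyntheticConfig(n_reactions=8, n_atoms_range=(4, 6), seed=42))


@pytest.fixture(scope="session")
def tiny_configs():
    """A deliberately small architecture for gradient checks and fast tests."""
    return (
        ModelConfig(n_psi_layers=2, encoder_heads=2, head_hidden=8, seed=5),
        FeaturizerConfig(n_embed=4, n_rbf=8),
    )


def randomize_heads(model: PSIModel, scale: float = 0.05, seed: int = 0) -> PSIModel:
    """Give the (zero-initialized) readout output layers random weights so the
    model's predictions deviate from the interpolation baseline."""
    rng = np.random.default_rng(seed)
    for name, p in model.named_parameters():
        if "fc2" in name:
            p.data = rng.normal(scale=scale, size=p.data.shape)
    return model


@pytest.fixture
def tiny_model(tiny_configs):
    mcfg, fcfg = tiny_configs
    return randomize_heads(PSIModel(mcfg, fcfg), seed=1)
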