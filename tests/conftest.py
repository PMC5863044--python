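import numpy as np
import pytest

from predflow.flow import FlowParams
from predflow.network import NetworkConfig
from predflow.stimuli import _make_texture


@pytest.fixture(scope="session")
def texture():
    """Multi-octave smooth texture, 120x160 grayscale in [0, 1]."""
    rng = np.random.default_rng(42)
    return _make_texture(rng, 200, 4)[:120, :160].mean(axis=2)


@pytest.fixture(scope="session")
def grid_points():
    """Interior grid of tracking points away from the frame border."""
    xs, ys = np.meshgrid(np.arange(35, 130, 12), np.arange(35, 90, 12))
    return np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)


@pytest.fixture
def tiny_config():
    """One-layer 8x8 network for elementwise checks."""
    return NetworkConfig(n_layers=1, stack_sizes=(3,), input_shape=(8, 8, 3), seed=0)


@pytest.fixture
def small_config():
    """Two-layer 16x16 network that trains in seconds."""
    return NetworkConfig(n_layers=2, stack_sizes=(3, 8), input_shape=(16, 16, 3), seed=1)


@pytest.fixture
def default_flow_params():
    return FlowParams()
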