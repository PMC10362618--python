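import numpy as np
import pytest

from foveaseg.autodiff import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_tensor(a, requires_grad=False, dtype=np.float64):
    t = Tensor(np.asarray(a, dtype=dtype))
    t.requires_grad = requires_grad
    return t


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small on-disk synthetic dataset shared across tests."""
    from foveaseg.synthetic_data import SynthConfig, generate_dataset

    root = tmp_path_factory.mktemp("tiles")
    cfg = SynthConfig(seed=11, n_train=8, n_test=4)
    generate_dataset(cfg, root)
    return root, cfg
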