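import numpy as np
import pytest

from rdblocks import nn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(autouse=True)
def _seed_params():
    """Deterministic layer initialisation for every test."""
    nn.seed_all(0)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """16 rendered synthetic scenes at 320 px, all tagged train."""
    from rdblocks.synth import generate_dataset
    root = tmp_path_factory.mktemp("ds16")
    manifest = generate_dataset(16, out_root=root, seed=5, image_size=320,
                                scenario="sunny", lesion_range=(2, 3))
    for rec in manifest.records:
        rec.split = "train"
    return manifest


def numgrad(f, x, eps=1e-3):
    """Central finite differences of sum(f()) w.r.t. tensor x."""
    g = np.zeros_like(x.data)
    it = np.nditer(x.data, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        old = x.data[idx]
        x.data[idx] = old + eps
        fp = float(f().data.sum())
        x.data[idx] = old - eps
        fm = float(f().data.sum())
        x.data[idx] = old
        g[idx] = (fp - fm) / (2 * eps)
    return g
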