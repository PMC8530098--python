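"""Shared fixtures: small synthetic datasets and tiny networks.

Everything is generated at test time into session-scoped temporary
directories; sizes are kept small so the full suite runs on one CPU.
"""

import numpy as np
import pytest

from parconvnet.archspec import lightweight_architecture
from parconvnet.model_runtime import instantiate
from parconvnet.synthetic import SyntheticTaskSpec, generate
from parconvnet.training import split_dataset


@pytest.fixture(scope="session")
def cells_small(tmp_path_factory):
    """Well-separated 3-class cell dataset at 32x32, split 75/25."""
    spec = SyntheticTaskSpec(task="cells", n_per_class=12, image_hw=(32, 32),
                             separability=1.0, noise_level=0.02, seed=101)
    manifest = generate(spec, tmp_path_factory.mktemp("cells_small"))
    return split_dataset(manifest, 0.75, seed=1)


@pytest.fixture(scope="session")
def ulcer_small(tmp_path_factory):
    """Well-separated 2-class ulcer dataset at 32x32, split 75/25."""
    spec = SyntheticTaskSpec(task="ulcer", n_per_class=12, image_hw=(32, 32),
                             separability=1.0, noise_level=0.02, seed=102)
    manifest = generate(spec, tmp_path_factory.mktemp("ulcer_small"))
    return split_dataset(manifest, 0.75, seed=1)


@pytest.fixture()
def tiny_net():
    """Smallest admissible network: 16x16 input, 2 classes."""
    return instantiate(lightweight_architecture((16, 16), 3, 2), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
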