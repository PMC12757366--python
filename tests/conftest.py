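import numpy as np
import pytest

from esadet.phantom import PhantomSpec, generate_corpus
from esadet.data import YoloDataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def micro_corpus(tmp_path_factory):
    """A very small phantom corpus shared across tests (30 images, 96px)."""
    root = tmp_path_factory.mktemp("micro_corpus")
    spec = PhantomSpec(canvas=96, counts={0: 10, 1: 10, 2: 10},
                       subjects=6, seed=7)
    manifest = generate_corpus(spec, root)
    return root, manifest


@pytest.fixture(scope="session")
def micro_datasets(micro_corpus):
    root, _ = micro_corpus
    return YoloDataset.open(root, "train"), YoloDataset.open(root, "val")
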