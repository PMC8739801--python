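import numpy as np
import pytest

from erj.data_model import LabeledDataset
from erj.extractor import ExtractorSpec
from erj.synthetic import (
    FixtureSpec,
    generate_feature_fixture,
    generate_image_fixture,
    make_base_pool_with_hidden_modes,
)


@pytest.fixture(scope="session")
def feature_fixture():
    """Small Gaussian-mixture dataset with one hidden mode per class."""
    spec = FixtureSpec(
        n_classes=3,
        modes_per_class=4,
        samples_per_class=50,
        hidden_modes_per_class=1,
        mode_separation=3.0,
        noise_scale=0.5,
        feature_dim=16,
        seed=1,
    )
    dataset, modes = generate_feature_fixture(spec)
    return dataset, modes, spec


@pytest.fixture(scope="session")
def image_splits():
    """Image fixture split into base/pool/test with a hidden mode."""
    spec = FixtureSpec(
        n_classes=3,
        modes_per_class=4,
        samples_per_class=50,
        hidden_modes_per_class=1,
        noise_scale=0.5,
        duplication_rate=0.2,
        level="image",
        image_shape=(16, 16),
        seed=2,
    )
    dataset, modes = generate_image_fixture(spec)
    base, pool, test, mode_of = make_base_pool_with_hidden_modes(
        dataset, modes, spec
    )
    return base, pool, test, mode_of, spec


@pytest.fixture
def tiny_spec():
    return ExtractorSpec(
        depth_preset="tiny", input_shape=(16, 16, 3), head_classes=3, seed=0
    )


@pytest.fixture
def random_feature_dataset():
    """Unstructured feature dataset helper for split arithmetic tests."""

    def make(n_classes: int, per_class: int, dim: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        n = n_classes * per_class
        return LabeledDataset(
            sample_ids=[f"s{i:05d}" for i in range(n)],
            payload=rng.normal(size=(n, dim)),
            labels=np.repeat(np.arange(n_classes), per_class),
            class_names=[f"c{j}" for j in range(n_classes)],
            payload_kind="feature",
        )

    return make
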