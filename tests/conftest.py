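import numpy as np
import pytest

from troposearch.fitness import TrainConfig
from troposearch.preprocessing import DatasetBundle, resize_to_input, split_dataset
from troposearch.search_space import build_default_space
from troposearch.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def space():
    return build_default_space()


@pytest.fixture(scope="session")
def small_bundle():
    """3-class synthetic dataset, resized to 64 x 64 x 3 and split."""
    bundle, _ = generate(SyntheticSpec(K=3, n_per_class=20, image_size=(64, 64), seed=1))
    bundle = DatasetBundle(
        images=[resize_to_input(img, (64, 64, 3)) for img in bundle.images],
        labels=bundle.labels,
        class_names=bundle.class_names,
    )
    return split_dataset(bundle, seed=0)


@pytest.fixture(scope="session")
def small_train_cfg():
    return TrainConfig(epochs=1, input_size=(64, 64, 3), seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
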