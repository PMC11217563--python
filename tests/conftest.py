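import numpy as np
import pytest

from rvit import models, synthetic, training


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_config():
    """A minimal but fully featured architecture for fast unit tests."""
    return models.ModelConfig(
        image_size=16, patch_size=4, in_channels=1, embed_dim=24, depth=2,
        heads=3, mlp_size=32, attention_dropout=0.1, rotations=4,
        stem_channels=2,
    )


@pytest.fixture()
def tiny_model(tiny_config):
    return models.build_model(tiny_config, seed=0)


@pytest.fixture(scope="session")
def phantom_data():
    """Small phantom dataset shared across tests (read-only)."""
    spec = synthetic.PhantomSpec(image_size=32, n_images=40, seed=7,
                                 lesion_axes=(5.0, 8.0))
    return synthetic.generate_dataset(spec)


@pytest.fixture(scope="session")
def trained_small_model():
    """A small rotation-averaged model trained briefly on salient phantoms.

    Shared by evaluation and Grad-CAM tests; training is kept short, so
    assertions on it are qualitative (better than chance, saliency inside
    the lesion) rather than about final accuracy.
    """
    spec = synthetic.uniform_orientation_spec(seed=31, n_images=240)
    data = synthetic.generate_dataset(spec)
    ds = training.LabelledImages(data.images, data.labels,
                                 synthetic.CLASS_NAMES)
    tr, va = training.split_train_val(ds.labels, 0.8, seed=3)
    model = models.build_model(models.small_study_config(), seed=3)
    config = training.TrainConfig(epochs=6, seed=3)
    history = training.train(model, ds.subset(tr), ds.subset(va), config)
    return model, data, ds, tr, va, history
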