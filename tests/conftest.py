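import numpy as np
import pytest

from cmpl.augmentation import AugmentationConfig
from cmpl.model import BackboneConfig
from cmpl.preprocessing import apply_normalizer, drop_missing_windows, fit_normalizer
from cmpl.synthetic_data import StreamSpec, default_motifs, make_dataset
from cmpl.training import TrainConfig


@pytest.fixture(scope="session")
def motifs():
    return default_motifs()


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small clean dataset: 10 windows/class labeled, 60 unlabeled (30% inactive)."""
    spec = StreamSpec(n_labeled_per_class=10, n_unlabeled=60, inactive_fraction=0.3, seed=7)
    return make_dataset(spec)


@pytest.fixture(scope="session")
def prepared_pools(tiny_dataset):
    """Preprocessed (labeled, unlabeled, test) pools from the tiny dataset."""
    labeled = drop_missing_windows(tiny_dataset.labeled)
    unlabeled = drop_missing_windows(tiny_dataset.unlabeled)
    stats = fit_normalizer(labeled)
    return (
        apply_normalizer(labeled, stats),
        apply_normalizer(unlabeled, stats),
        apply_normalizer(tiny_dataset.test, stats),
    )


@pytest.fixture
def small_model_cfg():
    return BackboneConfig(input_layout="4d", preset="small", feature_dim=16)


@pytest.fixture
def quick_train_cfg():
    """A handful of steps — just enough to exercise every code path."""
    return TrainConfig(
        batch_size=8,
        total_steps=6,
        student_lr=0.03,
        teacher_lr=0.03,
        warmup_frac=0.0,
        log_every=2,
        seed=3,
    )


@pytest.fixture
def aug_cfg():
    return AugmentationConfig(jitter_sd=0.05, flip_probability=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
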