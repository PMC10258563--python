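import numpy as np
import pytest

from neuroxai.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Small-but-structured dataset config used across unit tests."""
    return SyntheticConfig(grid_shape=(8, 8, 8), n_subjects=5,
                           trials_per_class_per_subject=6, n_classes=3,
                           n_blobs_per_class=2, blob_fwhm=2.0,
                           negative_blob_fraction=0.25, redundant_cluster_count=1,
                           subject_sd=0.1, noise_sd=0.5, noise_smoothing_fwhm=1.5,
                           seed=123)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def trained_small_model(small_dataset):
    """A decoder trained on the small dataset (shared, treated read-only)."""
    from neuroxai.decoder import DecoderConfig, build_model, train
    dataset, _ = small_dataset
    from neuroxai.synthetic import stack_trials
    X, y, _, _, _ = stack_trials(dataset.train)
    model = build_model(DecoderConfig(n_conv_layers=2, n_kernels=4, seed=17),
                        X.shape[1:], np.unique(y))
    train(model, (X, y), max_epochs=30, seed=17)
    return model
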