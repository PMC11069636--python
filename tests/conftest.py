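import numpy as np
import pandas as pd
import pytest

from thumbrot import (
    DatasetSpec,
    HandTemplate,
    ModelSpec,
    SkeletonConfig,
    SplitSpec,
    feature_table,
    generate_dataset,
    split_dataset,
    train,
)

# Reduced sweep used by the slower model-level tests: the full protocol's
# 15 subjects x 10 angles, but 10 frames per condition instead of 60.
_SMALL_SWEEP = dict(n_subjects=15, fps=10.0, duration_s=1.0)


@pytest.fixture(scope="session")
def skel():
    return SkeletonConfig()


@pytest.fixture(scope="session")
def template(skel):
    return HandTemplate.default(skel)


@pytest.fixture(scope="session")
def noiseless_frames(skel):
    return generate_dataset(DatasetSpec(**_SMALL_SWEEP, noise_sd=0.0, seed=7), skel=skel)


@pytest.fixture(scope="session")
def noisy_frames(skel):
    return generate_dataset(DatasetSpec(**_SMALL_SWEEP, noise_sd=0.005, seed=7), skel=skel)


@pytest.fixture(scope="session")
def noiseless_table(noiseless_frames):
    table, skipped = feature_table(noiseless_frames)
    assert not skipped
    return table


@pytest.fixture(scope="session")
def noisy_table(noisy_frames):
    table, skipped = feature_table(noisy_frames)
    assert not skipped
    return table


@pytest.fixture(scope="session")
def noisy_split(noisy_table):
    return split_dataset(noisy_table, SplitSpec(seed=7))


@pytest.fixture(scope="session")
def fitted_gbt(noisy_split):
    """A small but real gradient-boosted model on the noisy sweep."""
    train_tab, _ = noisy_split
    spec = ModelSpec(
        family="gradient_boosted_trees",
        search_space={"est__n_estimators": [60], "est__learning_rate": [0.1]},
        tuning_folds=3,
    )
    return train(spec, train_tab, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
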