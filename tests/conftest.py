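"""Shared fixtures: one synthetic table, one augmented dataset, two trained
models — session-scoped because generator and regressor training are the
expensive steps and every property they support is read-only."""

import pytest

from digestnn import (
    AugmentationConfig,
    RegressorSpec,
    SyntheticConfig,
    TrainConfig,
    augment_ensemble,
    generate_protein_table,
    train_regressor,
)


@pytest.fixture(scope="session")
def table0():
    return generate_protein_table(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def dataset0(table0):
    return augment_ensemble(table0, AugmentationConfig(seed=0))


@pytest.fixture(scope="session")
def trained_full(dataset0):
    return train_regressor(dataset0, RegressorSpec.full(), TrainConfig(seed=0))


@pytest.fixture(scope="session")
def trained_simplified(dataset0):
    return train_regressor(dataset0, RegressorSpec.simplified(), TrainConfig(seed=0))
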