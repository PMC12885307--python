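import numpy as np
import pytest

import biradsrules as br
from biradsrules.schema_io import BENIGN, MALIGNANT
from biradsrules.synthetic_data import PlantedBlock, SynthConfig


@pytest.fixture(scope="session")
def schema():
    return br.default_schema()


@pytest.fixture(scope="session")
def feature_index(schema):
    return {name: i for i, name in enumerate(schema.names)}


def make_recovery_config(feature_index, seed=0, n_class=30, n_block=20,
                         coherence=1.0, label_noise=0.0):
    """Clean two-phenotype instance: each class dominated by one 3-column
    block on high-arity descriptors with background-rare pattern values."""
    cb = (
        feature_index["Shape"],
        feature_index["Echo pattern"],
        feature_index["Posterior feature"],
    )
    cm = (
        feature_index["Echo pattern"],
        feature_index["Calcification in mass"],
        feature_index["Ducts changes"],
    )
    blocks = (
        PlantedBlock(cb, (1, 4, 1), BENIGN, n_block, coherence),
        PlantedBlock(cm, (5, 3, 2), MALIGNANT, n_block, coherence),
    )
    return SynthConfig(
        n_benign=n_class,
        n_malignant=n_class,
        blocks=blocks,
        label_noise=label_noise,
        seed=seed,
    )


@pytest.fixture
def recovery_config(feature_index):
    return make_recovery_config(feature_index)


@pytest.fixture
def small_table():
    """A small imbalanced table with clean planted structure."""
    cfg = br.default_config(
        n_benign=60, n_malignant=25, coherence=1.0, label_noise=0.0, seed=3
    )
    table, _ = br.generate(cfg)
    return table
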