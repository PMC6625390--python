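import numpy as np
import pandas as pd
import pytest

from ppinet import (
    FixtureConfig,
    ForestConfig,
    InteractionForest,
    LabeledFeatureTable,
    generate_fixture,
)
from ppinet.features import FEATURE_NAMES

DEFAULT_SEED = 17


def toy_features(n, signal, seed=0):
    """Feature rows with go_bp_sim centered on `signal`, rest benign noise."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        0.0,
        index=pd.MultiIndex.from_tuples(
            [(f"A{seed:02d}{i:04d}", f"B{seed:02d}{i:04d}") for i in range(n)],
            names=["protein_a", "protein_b"],
        ),
        columns=list(FEATURE_NAMES),
    )
    frame["go_bp_sim"] = np.clip(signal + rng.normal(scale=0.05, size=n), 0, 1)
    frame["coexpression_pcc"] = rng.uniform(-0.2, 0.2, size=n)
    frame["rmsd"] = rng.uniform(0, 5, size=n)
    return frame


@pytest.fixture(scope="session")
def bundle():
    """The default planted-truth universe (in memory)."""
    return generate_fixture(FixtureConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def feature_table(bundle):
    """Features for planted pairs followed by the negative pool."""
    return bundle.feature_table()


@pytest.fixture(scope="session")
def split_features(bundle, feature_table):
    positives = feature_table.iloc[: len(bundle.gold)]
    pool = feature_table.iloc[len(bundle.gold):]
    return positives, pool


@pytest.fixture(scope="session")
def balanced_table(split_features):
    """Planted positives + an equal-size random draw from the negative pool."""
    positives, pool = split_features
    rng = np.random.default_rng(DEFAULT_SEED)
    take = np.sort(rng.choice(len(pool), size=len(positives), replace=False))
    return LabeledFeatureTable.from_tables(positives, pool.iloc[take])


@pytest.fixture(scope="session")
def fitted_results(balanced_table):
    return InteractionForest(balanced_table, ForestConfig(seed=DEFAULT_SEED)).fit()
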