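import warnings

import pytest

from lincnet import (
    SimulationConfig,
    extract_features,
    simulate_all,
    train_coding_model,
    train_hexamer_table,
)

warnings.filterwarnings("ignore", message="no power reached")


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study (seed 1): catalog, truth, expression panels."""
    return simulate_all(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def trained(bundle):
    """(hexamer table, coding model) fitted on the bundle's training sets."""
    hexamers = train_hexamer_table(bundle.coding_train, bundle.noncoding_train)
    feats = [extract_features(s, hexamers) for s in bundle.coding_train + bundle.noncoding_train]
    labels = [1] * len(bundle.coding_train) + [0] * len(bundle.noncoding_train)
    model = train_coding_model(feats, labels)
    return hexamers, model
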