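import numpy as np
import pandas as pd
import pytest

import odorhedonics as oh
from odorhedonics.synthetic import GeneratorConfig, simulate_study


@pytest.fixture(scope="session")
def published_vocab():
    return oh.HedonicVocabulary.published_subset()


@pytest.fixture()
def small_profile():
    """Three odorants over three descriptors with known tones."""
    return pd.DataFrame(
        {
            "fruity": [36.0, 0.0, 5.0],
            "sweet": [8.0, 0.0, 50.0],
            "fishy": [0.0, 60.0, 0.0],
        },
        index=["benzyl_acetate", "tma", "mixed"],
    )


@pytest.fixture(scope="session")
def planted_study():
    """Default-condition synthetic study with eq11-planted truth."""
    cfg = GeneratorConfig(seed=11, n_molecules=200, n_descriptors=40)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def planted_vocab(planted_study):
    return oh.HedonicVocabulary(dict(planted_study["tones"]))
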