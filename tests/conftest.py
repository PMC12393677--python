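import numpy as np
import pandas as pd
import pytest

from lbptrial import synth


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared across read-only tests."""
    return synth.generate_cohort(
        synth.CohortConfig(n_participants=60, seed=11))


@pytest.fixture(scope="session")
def taxonomy():
    return synth.default_taxonomy()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_taxonomy():
    """Minimal 5-species taxonomy for hand-built compositional fixtures."""
    return pd.DataFrame(
        {
            "genus": ["Lactobacillus", "Lactobacillus", "Lactobacillus",
                      "Gardnerella", "Prevotella"],
            "is_lactobacillus": [True, True, True, False, False],
        },
        index=["Lactobacillus crispatus", "Lactobacillus iners",
               "Lactobacillus jensenii", "Gardnerella vaginalis",
               "Prevotella bivia"],
    )
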