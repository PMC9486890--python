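import numpy as np
import pandas as pd
import pytest

from seroclone import (CohortConfig, RepertoireConfig, simulate_repertoire,
                       simulate_serology_cohort)


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (seeded)."""
    return simulate_serology_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def repertoire():
    """Default synthetic repertoire with c_call-based isotype column."""
    rep = simulate_repertoire(RepertoireConfig(seed=11))
    rep.cells["dominant_isotype"] = rep.cells["c_call"]
    return rep


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
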