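import numpy as np
import pandas as pd
import pytest

import pancansig as ps


@pytest.fixture(scope="session")
def disjoint_signatures() -> pd.DataFrame:
    """Three signatures with disjoint channel support on 12 channels.

    Disjoint support makes attribution fractions exact 0/1 indicators, so
    clonality recovery and extraction have analytically known answers.
    """
    S = np.zeros((12, 3))
    S[0:4, 0] = [0.4, 0.3, 0.2, 0.1]
    S[4:8, 1] = [0.1, 0.2, 0.3, 0.4]
    S[8:12, 2] = 0.25
    return pd.DataFrame(S, index=[f"ch{i}" for i in range(12)],
                        columns=["P1", "P2", "P3"])


@pytest.fixture(scope="session")
def small_cohort(disjoint_signatures):
    """A 60-sample cohort generated from the disjoint signatures."""
    spec = ps.CohortSpec(n_samples=60, n_channels=12, n_signatures=3, seed=101)
    return ps.gen_cohort(spec, disjoint_signatures)
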