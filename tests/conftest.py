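import numpy as np
import pandas as pd
import pytest

import immunosig as im


@pytest.fixture(scope="session")
def planted_cohort() -> im.SyntheticCohort:
    """Small cohort with a fully penetrant, strongly shifted signature."""
    return im.generate_cohort(
        im.CohortConfig(n_probes=200, effect_size=3.0, penetrance=1.0, seed=7)
    )


@pytest.fixture(scope="session")
def default_cohort_small() -> im.SyntheticCohort:
    """Generator defaults (heterogeneous down-regulation) at a reduced probe count."""
    return im.generate_cohort(im.CohortConfig(n_probes=800, seed=3))


@pytest.fixture()
def toy_expression() -> pd.DataFrame:
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        rng.normal(size=(6, 8)),
        index=[f"p{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(8)],
    )
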