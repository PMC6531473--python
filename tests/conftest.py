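import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import mxi

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def small_matrix():
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(4)]
    rng = np.random.default_rng(5)
    return mxi.ExpressionMatrix(
        pd.DataFrame(rng.normal(5, 1, size=(6, 4)), index=genes, columns=samples)
    )


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic study, shared read-only across tests."""
    return mxi.simulate_cohort(mxi.SyntheticCohortSpec(seed=11))


@pytest.fixture(scope="session")
def bundle_scores(bundle):
    """Pooled tumor+normal index scores for the default bundle."""
    tables = [
        mxi.compute_index(m, bundle.signature).table
        for m in bundle.expression.values()
    ]
    return mxi.IndexTable(pd.concat(tables))
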