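import numpy as np
import pandas as pd
import pytest

import codshift as cs


@pytest.fixture(scope="session")
def taxonomy():
    return cs.default_taxonomy()


@pytest.fixture(scope="session")
def cohort_100k():
    """One mid-size synthetic cohort with the default planted shift."""
    return cs.generate_cohort(cs.default_config(n_records=100_000, seed=11))


@pytest.fixture(scope="session")
def retained_100k(cohort_100k, taxonomy):
    retained, _ = cs.apply_exclusions(cohort_100k, taxonomy)
    return retained


def random_cube(rng: np.random.Generator, n_years=4, n_months=5, n_causes=3, lam=40.0) -> cs.CountCube:
    """A dense random count cube for property tests."""
    years = list(range(2000, 2000 + n_years))
    months = list(range(n_months))
    causes = [f"c{k}" for k in range(n_causes)]
    idx = pd.MultiIndex.from_product([years, months], names=["year", "month"])
    counts = rng.poisson(lam, size=(len(idx), n_causes))
    # guarantee every year has at least one death so year proportions exist
    counts[:: n_months, 0] += 1
    return cs.CountCube(pd.DataFrame(counts, index=idx, columns=causes))
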