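import pandas as pd
import pytest

import frailty_audit as fa


@pytest.fixture(scope="session")
def cohort_small() -> pd.DataFrame:
    """Complete-data cohort used across test modules (read-only)."""
    return fa.generate_cohort(fa.CohortSpec(n_participants=2000, seed=11))


@pytest.fixture(scope="session")
def indexed_small(cohort_small) -> pd.DataFrame:
    """Cohort with all derived columns, indices, statuses and bias columns."""
    built = fa.FrailtyIndexBuilder().fit(cohort_small).transform(cohort_small)
    return fa.BiasDecomposer().fit(built).transform(built)


@pytest.fixture(scope="session")
def cohort_large() -> pd.DataFrame:
    """Larger cohort for Monte-Carlo oracles."""
    return fa.generate_cohort(fa.CohortSpec(n_participants=20000, seed=7))
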