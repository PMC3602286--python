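import numpy as np
import pandas as pd
import pytest

from cesdimpute import ITEM_COLUMNS, generate_cohort


def items_frame(rows) -> pd.DataFrame:
    """Build an item DataFrame from a list of 20-value rows (None = missing)."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in r] for r in rows]
    )
    return pd.DataFrame(arr, columns=list(ITEM_COLUMNS))


def random_partial_rows(rng, n_rows: int, max_missing: int = 6) -> pd.DataFrame:
    """Random item rows with 0..max_missing missing cells each."""
    vals = rng.integers(0, 4, size=(n_rows, 20)).astype(float)
    for i in range(n_rows):
        k = rng.integers(0, max_missing + 1)
        if k:
            vals[i, rng.choice(20, size=k, replace=False)] = np.nan
    return pd.DataFrame(vals, columns=list(ITEM_COLUMNS))


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Complete synthetic cohort shared by the cheaper engine tests."""
    return generate_cohort(n=600, seed=1234)


@pytest.fixture(scope="session")
def medium_cohort() -> pd.DataFrame:
    """Complete cohort at the parameter-recovery desk scale."""
    return generate_cohort(n=2000, seed=4321)
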