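import numpy as np
import pandas as pd
import pytest

from immunoscore import CohortConfig, cohort_to_frame, generate_cohort

# printed response-by-category contingency tables (rows = score groups,
# columns = [no pCR, pCR]) and their published exact p-values
TABLE2 = {
    "isb_3group": ([[34, 6], [11, 9], [21, 19]], 0.0035),
    "isb_2group": ([[34, 6], [32, 28]], 0.0012),
    "is_3group": ([[30, 6], [25, 12], [7, 10]], 0.0096),
    "is_2group": ([[55, 18], [7, 10]], 0.0093),
}


@pytest.fixture(scope="session")
def default_cohort_frame() -> pd.DataFrame:
    return cohort_to_frame(generate_cohort(CohortConfig(seed=7)))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
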