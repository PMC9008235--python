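import numpy as np
import pytest

from nmachart.datasets import betaine_dataset

# Published per-subgroup values of the Betaine example (2-decimal precision):
# transformed subgroup means and their moving averages (span 3 for the lower
# endpoint, span 5 for the upper).  The head rows of the published MA columns
# (before a full window exists) follow an unexplained convention and are
# excluded from cell-for-cell checks.
PRINTED_TMEAN_LOWER = np.array([
    4.78, 4.40, 4.16, 3.23, 3.58, 3.83, 4.02, 4.75, 3.10, 4.58, 4.63, 4.44,
    4.39, 3.85, 4.96, 3.96, 4.26, 4.52, 4.31, 4.80, 3.51, 4.16, 3.58, 3.98,
])
PRINTED_TMEAN_UPPER = np.array([
    5.06, 4.91, 4.61, 3.91, 3.63, 4.45, 4.41, 2.83, 3.41, 3.09, 3.11, 4.21,
    3.06, 3.65, 3.88, 2.67, 2.44, 2.95, 3.44, 2.70, 3.53, 3.89, 5.14, 3.71,
])
PRINTED_MA_LOWER = np.array([
    4.16, 4.16, 4.45, 3.93, 3.66, 3.55, 3.81, 4.20, 3.96, 4.14, 4.11, 4.55,
    4.49, 4.23, 4.40, 4.25, 4.39, 4.25, 4.36, 4.55, 4.21, 4.16, 3.75, 3.91,
])
PRINTED_MA_UPPER = np.array([
    3.70, 3.70, 3.70, 3.70, 4.43, 4.30, 4.21, 3.85, 3.75, 3.64, 3.37, 3.33,
    3.38, 3.42, 3.58, 3.49, 3.14, 3.12, 3.07, 2.84, 3.01, 3.30, 3.74, 3.79,
])


@pytest.fixture(scope="session")
def betaine():
    return betaine_dataset()


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
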