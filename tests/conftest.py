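import sys
from pathlib import Path

import pytest

from uorfpred import CoefficientSet

sys.path.insert(0, str(Path(__file__).parent))  # make reference.py importable

# Moderate ground-truth coefficients on the raw feature scales
# (A in 1..6, B in 0..3, C in tens-hundreds of nt, D in percent).
TRUE_BETA = (
    -2.0, 0.8, 0.5, 0.004, 0.01,
    0.1, -0.001, -0.01, 0.002, 0.05, -0.0001,
)


@pytest.fixture
def true_beta() -> CoefficientSet:
    return CoefficientSet(beta=TRUE_BETA)
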