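import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from emtsig.matrix_io import ExpressionMatrix

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable


@pytest.fixture
def tiny_counts() -> ExpressionMatrix:
    """2-gene x 2-sample counts matrix with values 1..4 in row-major order."""
    df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["gA", "gB"], columns=["s1", "s2"])
    return ExpressionMatrix(df, "counts")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
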