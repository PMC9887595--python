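import warnings

import numpy as np
import pytest

from arbic.matrix_io import ExpressionMatrix


@pytest.fixture(autouse=True)
def _quiet_narrow_matrix_warning():
    """Small test matrices always trigger the narrow-matrix advisory."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="matrix has n=", category=RuntimeWarning
        )
        warnings.filterwarnings(
            "ignore", message="q\\*n < 1", category=RuntimeWarning
        )
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix(rng) -> ExpressionMatrix:
    vals = rng.standard_normal((6, 9))
    return ExpressionMatrix(
        vals,
        gene_ids=[f"g{i}" for i in range(6)],
        condition_ids=[f"c{j}" for j in range(9)],
    )
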