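import numpy as np
import pytest

from benfordrna import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20160809)


@pytest.fixture
def small_counts(rng):
    """A 20-gene x 50-sample integer count matrix with lognormal structure."""
    values = np.round(10 ** rng.normal(2.0, 1.0, size=(20, 50))).astype(float)
    return ExpressionMatrix(
        values=values,
        gene_ids=tuple(f"g{i:02d}" for i in range(20)),
        sample_ids=tuple(f"s{j:02d}" for j in range(50)),
        metric="raw",
    )
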