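import numpy as np
import pandas as pd
import pytest

from clustercall import (
    ClusterMetadata,
    ExpressionMatrix,
    ReferenceMatrix,
    SyntheticSpec,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_dataset():
    """The default 5-type planted fixture (query, meta, reference, markers)."""
    return generate_dataset(SyntheticSpec(seed=7))


@pytest.fixture
def tiny_matrix():
    """4 genes x 6 cells, two 3-cell clusters, hand-enumerable values."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.uniform(0, 4, size=(4, 6)),
        index=[f"g{i}" for i in range(4)],
        columns=[f"c{i}" for i in range(6)],
    )
    mat = ExpressionMatrix(values, is_log=True)
    meta = ClusterMetadata(
        pd.DataFrame({"cluster": ["A"] * 3 + ["B"] * 3}, index=values.columns)
    )
    return mat, meta


@pytest.fixture
def small_reference():
    rng = np.random.default_rng(3)
    values = pd.DataFrame(
        rng.uniform(0, 5, size=(20, 3)),
        index=[f"g{i:02d}" for i in range(20)],
        columns=["B", "NK", "T"],
    )
    return ReferenceMatrix(values, is_log=True)
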