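import numpy as np
import pandas as pd
import pytest

from otupairs.community import BinaryCommunityMatrix, ReadCountTable


@pytest.fixture
def tiny_counts() -> ReadCountTable:
    df = pd.DataFrame(
        {
            "otuA": [100, 10, 0, 50],
            "otuB": [4, 10, 0, 0],
            "otuC": [0, 5, 30, 5],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return ReadCountTable(df)


@pytest.fixture
def tiny_binary() -> BinaryCommunityMatrix:
    """10 samples x 8 OTUs, fixed by seed; first OTU occupies 3 samples."""
    rng = np.random.default_rng(42)
    mat = (rng.random((10, 8)) < 0.4).astype(np.uint8)
    mat[:, 0] = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
    return BinaryCommunityMatrix(
        mat, [f"s{i}" for i in range(10)], [f"o{j}" for j in range(8)]
    )


@pytest.fixture
def small_matrix_4x5() -> BinaryCommunityMatrix:
    rng = np.random.default_rng(7)
    mat = (rng.random((4, 5)) < 0.5).astype(np.uint8)
    return BinaryCommunityMatrix(
        mat, [f"s{i}" for i in range(4)], [f"o{j}" for j in range(5)]
    )
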