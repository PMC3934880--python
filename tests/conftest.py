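import numpy as np
import pandas as pd
import pytest

from bsnorm import CountMatrix, ScaleSet


@pytest.fixture
def small_counts() -> CountMatrix:
    """3 genes × 2 samples with library sizes 100 and 200."""
    return CountMatrix(
        pd.DataFrame(
            {"s1": [50, 30, 20], "s2": [100, 60, 40]}, index=["g1", "g2", "g3"]
        )
    )


@pytest.fixture
def scales_15(small_counts) -> ScaleSet:
    """User scales Z = (1.0, 1.5) anchored at s1."""
    return ScaleSet(["s1", "s2"], [1.0, 1.5], kind="user", reference="s1")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240219)
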