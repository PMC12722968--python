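import numpy as np
import pandas as pd
import pytest

from pdpipe import FeatureTable, make_worked_toy, preprocess


@pytest.fixture
def toy() -> FeatureTable:
    """The hard-coded 12-row, 4-feature cross-module fixture."""
    return make_worked_toy()


@pytest.fixture
def toy_norm(toy):
    """Preprocessed toy fixture (no missing cells, nothing dropped)."""
    norm, _ = preprocess(toy)
    return norm


@pytest.fixture
def small_table() -> FeatureTable:
    """Tiny 3-row table for direct-readback checks."""
    return FeatureTable(
        values=pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [5.0, 5.0, 5.0]}),
        labels=np.array([1, 0, 1]),
    )
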