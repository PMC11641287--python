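import numpy as np
import pandas as pd
import pytest

from circaxis import ExpressionMatrix, SampleDesign, SyntheticConfig, generate


@pytest.fixture
def small_matrix():
    """2 features x 4 samples with a clean tumor/normal contrast."""
    values = pd.DataFrame(
        [[10.0, 10.2, 8.0, 8.1], [7.0, 7.1, 7.0, 7.1]],
        index=["f1", "f2"],
        columns=["t1", "t2", "n1", "n2"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def small_design():
    groups = pd.Series(
        ["tumor", "tumor", "normal", "normal"],
        index=pd.Index(["t1", "t2", "n1", "n2"], name="sample_id"),
    )
    return SampleDesign(groups=groups)


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic bundle, shared across tests (read-only)."""
    return generate(SyntheticConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
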