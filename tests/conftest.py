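import numpy as np
import pandas as pd
import pytest

from simkern.datasets import Dataset, FeatureMeta
from simkern.models import get_model


@pytest.fixture(scope="session")
def netflow_model():
    return get_model("netflow")


@pytest.fixture(scope="session")
def boolean_model():
    return get_model("boolean")


@pytest.fixture(scope="session")
def flowering_model():
    return get_model("flowering")


@pytest.fixture(scope="session")
def radiation_model():
    return get_model("radiation")


@pytest.fixture(scope="session")
def netflow_dataset(netflow_model):
    return netflow_model.generate(120, seed=42)


@pytest.fixture(scope="session")
def boolean_dataset(boolean_model):
    return boolean_model.generate(200, seed=42)


@pytest.fixture(scope="session")
def flowering_small(flowering_model):
    return flowering_model.generate(60, seed=42)


@pytest.fixture
def toy_classification_dataset():
    """Tiny hand-made classification dataset with a categorical column."""
    rng = np.random.default_rng(0)
    n = 40
    X = pd.DataFrame({
        "x1": rng.normal(size=n),
        "flag": rng.integers(0, 2, size=n),
        "colour": rng.choice(["red", "green", "blue"], size=n),
    })
    y = np.where(X["x1"] + X["flag"] > 0.3, "pos", "neg").astype(object)
    meta = [FeatureMeta("x1", "continuous"),
            FeatureMeta("flag", "binary"),
            FeatureMeta("colour", "categorical",
                        levels=("red", "green", "blue"))]
    return Dataset([f"t{i:03d}" for i in range(n)], X, y, meta,
                   task="classification", model="toy")
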