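import numpy as np
import pandas as pd
import pytest

from forestclust import FeatureSchema, MixedTable


def make_random_table(seed: int, n: int = 8, with_missing: bool = False) -> MixedTable:
    """A small table exercising every feature kind (used for round-trips)."""
    rng = np.random.default_rng(seed)
    schema = [
        FeatureSchema("age", "continuous"),
        FeatureSchema("cn", "integer"),
        FeatureSchema("grade", "ordinal", ("G1", "G2", "G3")),
        FeatureSchema("subtype", "nominal", ("lumA", "lumB", "basal", "her2")),
        FeatureSchema("er", "binary", ("neg", "pos")),
    ]
    df = pd.DataFrame(
        {
            "age": rng.normal(60, 10, n).round(3),
            "cn": rng.integers(0, 8, n).astype(float),
            "grade": rng.choice(["G1", "G2", "G3"], n),
            "subtype": rng.choice(["lumA", "lumB", "basal", "her2"], n),
            "er": rng.choice(["neg", "pos"], n),
        }
    )
    if with_missing:
        df.loc[0, "age"] = np.nan
        df.loc[1, "subtype"] = None
    labels = rng.integers(0, 2, n)
    return MixedTable(df, schema, labels=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    return make_random_table(0, n=10)
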