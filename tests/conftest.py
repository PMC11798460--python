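import numpy as np
import pandas as pd
import pytest

from cropvote.panel import CropPanel
from cropvote.synthetic import (
    CategoricalFeatureSpec,
    NumericFeatureSpec,
    PanelSpec,
    generate_panel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """20 regions x 10 steps, two numeric drivers + one categorical."""
    return PanelSpec(
        n_regions=20,
        n_steps=10,
        numeric_features=[
            NumericFeatureSpec("rain", mean=50.0, sd=10.0, ar1=0.6),
            NumericFeatureSpec("temp", mean=20.0, sd=3.0, ar1=0.7),
        ],
        categorical_features=[
            CategoricalFeatureSpec("soil", ["clay", "loam", "sand"], [0.2, 0.0, -0.3])
        ],
        signal_weights={"rain": 0.05, "temp": -0.2},
        noise_sd=0.5,
        minority_fraction=0.2,
        seed=7,
    )


@pytest.fixture
def small_panel(small_spec):
    return generate_panel(small_spec)


@pytest.fixture
def tiny_panel():
    """Hand-built 2-region panel for exact-value preprocessing tests."""
    df = pd.DataFrame(
        {
            "region_id": ["A"] * 3 + ["B"] * 3,
            "t": [0, 1, 2, 0, 1, 2],
            "x": [0.0, 5.0, 10.0, 2.0, 2.0, 6.0],
            "crop": ["loam", "clay", "loam", "sand", "loam", "clay"],
            "yield": [5.0, 6.0, 7.0, 4.0, 5.0, 6.0],
            "label": [0, 0, 0, 1, 1, 0],
        }
    )
    return CropPanel(df, ["x"], ["crop"])
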