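import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pasvm.datasets import ExpressionDataset, SyntheticSpec, generate_synthetic

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def synth_small() -> ExpressionDataset:
    """The default synthetic regime: 60 samples, 10 informative features,
    10 exact redundant copies, 480 irrelevant, effect size 2."""
    return generate_synthetic(SyntheticSpec(seed=1))


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """Three clearly separated features on 12 samples, two classes."""
    rng = np.random.default_rng(7)
    labels = np.array(["a"] * 6 + ["b"] * 6)
    shift = np.where(labels == "b", 4.0, 0.0)
    matrix = rng.standard_normal((12, 3)) + shift[:, None]
    return ExpressionDataset(
        matrix, labels, ["g1", "g2", "g3"], [f"s{i}" for i in range(12)]
    )
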