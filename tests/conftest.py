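import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from weakmiml import Bag, LabelMatrix, LabelSpace, MIMLDataset
from weakmiml.synthetic import SyntheticSpec, generate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_bag(bag_id, points):
    """1-D or k-D bag from a list of instance coordinate lists."""
    return Bag(bag_id, np.atleast_2d(np.asarray(points, dtype=float)))


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic 50-bag, 10-label synthetic dataset with full labels."""
    ds, _ = generate_dataset(SyntheticSpec(m=50, L=10, dim=24, seed=11))
    return ds


@pytest.fixture(scope="session")
def tiny_dataset():
    """Hand-built 4-bag, 3-label dataset for exact bookkeeping checks."""
    bags = [
        make_bag("b0", [[0.0, 0.0], [1.0, 0.0]]),
        make_bag("b1", [[0.0, 1.0]]),
        make_bag("b2", [[5.0, 5.0], [6.0, 5.0], [5.0, 6.0]]),
        make_bag("b3", [[5.0, 4.0]]),
    ]
    Y = LabelMatrix(
        np.array([[1, 0, 1], [1, 1, 0], [0, 1, 1], [1, 0, 1]]), "full"
    )
    space = LabelSpace(["GO:0000001", "GO:0000002", "GO:0000003"])
    return MIMLDataset(bags, Y, space)
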