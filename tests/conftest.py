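import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def paired_ten_blocks():
    """Ten paired scores with one zero difference and T+ = 32, T- = 13."""
    y1 = np.array([77.9, 89.2, 78.2, 50.0, 94.5, 73.1, 77.5, 70.6, 89.4, 77.6])
    y2 = np.array([77.2, 66.0, 69.2, 58.2, 74.0, 88.3, 77.5, 74.6, 78.4, 72.2])
    return y1, y2


@pytest.fixture
def rank_order_groups():
    """Nine values whose low-to-high group labels read CECCECEEE."""
    values = np.arange(1.0, 10.0)
    labels = list("CECCECEEE")
    e = values[[i for i, l in enumerate(labels) if l == "E"]]
    c = values[[i for i, l in enumerate(labels) if l == "C"]]
    return e, c


@pytest.fixture
def bivariate_examples():
    """Two small bivariate data sets: one tie-free, one with tie clusters."""
    tie_free = (
        [-5.6, -0.5, 2.1, 3.6, 4.1],
        [1.5, 4.7, 1.1, 6.2, 5.9],
    )
    with_ties = (
        [-5.6, 1.3, 1.3, 3.9, 3.9],
        [1.5, 4.7, 1.1, 6.1, 6.1],
    )
    return tie_free, with_ties


@pytest.fixture
def ordered_3x4_table():
    """3x4 ordered contingency table with N = 158 observations."""
    return np.array(
        [
            [38, 4, 5, 0],
            [6, 40, 1, 2],
            [4, 8, 20, 30],
        ]
    )
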