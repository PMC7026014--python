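import numpy as np
import pytest

from tsmc.coalescent import CoalescentState
from tsmc.mixture import MixtureDataset, MixtureParams, MixturePriorSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_group_data():
    """Twenty points from a well-separated two-component mixture."""
    r = np.random.default_rng(7)
    y = np.concatenate([r.normal(-2, 1, 10), r.normal(2, 1, 10)])
    return MixtureDataset.from_observations(y)


@pytest.fixture
def mixture_priors(two_group_data):
    return MixturePriorSpec.from_data(two_group_data)


@pytest.fixture
def three_comp_params():
    return MixtureParams([-1.0, 1.5, 4.0], [0.8, 2.0, 1.1], [0.25, 0.4, 0.35])


@pytest.fixture
def four_leaf_tree():
    """Fixed ultrametric 4-leaf genealogy: ((A,B),(C,D)) with distinct
    coalescence heights."""
    return CoalescentState(
        labels=["A", "B", "C", "D"],
        children=[[0, 1], [2, 3], [4, 5]],
        heights=[0.2, 0.35, 1.1],
        theta=0.3,
    )
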