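import numpy as np
import pytest

from pvhist import DesignInfo, FeatureMatrix


@pytest.fixture
def two_group_design():
    """Balanced two-group design, 3 samples per group."""
    return DesignInfo(group=("A", "A", "A", "B", "B", "B"))


@pytest.fixture
def paired_design():
    """Three pairs, one member per group."""
    return DesignInfo(
        group=("A", "B", "A", "B", "A", "B"),
        pair_id=("p1", "p1", "p2", "p2", "p3", "p3"),
    )


@pytest.fixture
def small_matrix():
    """6 x 40 standard-normal matrix (null everywhere)."""
    rng = np.random.default_rng(42)
    return FeatureMatrix.from_arrays(rng.standard_normal((6, 40)))
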