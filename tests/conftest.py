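import numpy as np
import pytest

from cpglife.io_formats import phylogeny_from_string


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — covariance [[2,1,0],[1,2,0],[0,0,2]]."""
    return phylogeny_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return phylogeny_from_string("(A:1,B:1,C:1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
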