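import numpy as np
import pytest

from cyanosym.sequence_io import Feature, FeatureTable
from cyanosym.synthetic import printed_retention_fixture


@pytest.fixture(scope="session")
def printed_fixture():
    """Ortho matrix + annotation map encoding the published retention counts."""
    return printed_retention_fixture()


@pytest.fixture
def simple_features():
    return FeatureTable(
        [
            Feature("g1", "chr", 0, 100, "+", "CDS"),
            Feature("g2", "chr", 150, 400, "-", "CDS"),
            Feature("r1", "chr", 500, 580, "+", "rRNA"),
            Feature("t1", "chr", 700, 780, "-", "tRNA"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
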