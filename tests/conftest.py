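import numpy as np
import pytest
from hypothesis import settings

from transbic.core import DOWN, UP, BTPBicluster, ExpressionMatrix

settings.register_profile("ci", derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture
def bucket_matrix():
    """Five genes over conditions c1..c5 with a 4-gene BTP-bicluster.

    Genes g1, g2, g4 decrease along the bucket order <{c1}, {c4}, {c3,c5}>
    (values over {c3,c5} below c4 below c1); g5 shows the reversed trend.
    g3 and column c2 carry no structure.
    """
    values = np.array(
        [
            [9.0, 5.0, 1.0, 4.0, 2.0],  # g1 down
            [8.0, 1.0, 2.0, 5.0, 3.0],  # g2 down
            [5.0, 2.0, 9.0, 1.0, 7.0],  # g3 unrelated
            [7.0, 9.0, 1.0, 3.0, 2.0],  # g4 down
            [0.0, 4.0, 8.0, 5.0, 9.0],  # g5 up
        ]
    )
    return ExpressionMatrix(
        values,
        ("g1", "g2", "g3", "g4", "g5"),
        ("c1", "c2", "c3", "c4", "c5"),
    )


@pytest.fixture
def bucket_bicluster():
    """The ground-truth bicluster of ``bucket_matrix`` in stored order."""
    return BTPBicluster(
        gene_members=frozenset({0, 1, 3, 4}),
        directions={0: DOWN, 1: DOWN, 3: DOWN, 4: UP},
        partition=((0,), (3,), (2, 4)),
        p_value=0.001,
        support=4,
    )
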