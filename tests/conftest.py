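import numpy as np
import pytest

from poolscan.io import PoolSpec, PoolSnpTable


@pytest.fixture
def four_pools():
    return [
        PoolSpec("fieldA", "resistant", 30),
        PoolSpec("fieldB", "resistant", 30),
        PoolSpec("labA", "susceptible", 28),
        PoolSpec("labB", "susceptible", 30),
    ]


def make_table(pools, ref_counts, alt_counts, scaffold="scaf1", positions=None):
    """Small hand-built SNP table for unit tests."""
    ref_counts = np.atleast_2d(np.asarray(ref_counts))
    alt_counts = np.atleast_2d(np.asarray(alt_counts))
    L = ref_counts.shape[0]
    positions = np.asarray(positions if positions is not None
                           else np.arange(1, L + 1) * 100)
    return PoolSnpTable(
        pools,
        np.array([scaffold] * L, dtype=object),
        positions,
        np.array(["A"] * L, dtype=object),
        np.array(["T"] * L, dtype=object),
        ref_counts.astype(np.int64),
        alt_counts.astype(np.int64),
    )


@pytest.fixture
def two_pools():
    return [PoolSpec("a", "resistant", 30), PoolSpec("b", "susceptible", 30)]
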