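import numpy as np
import pytest

from paretomotif.core import SequenceSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_seqs():
    """Six 60-bp sequences with an identical GATTACCA planted at known starts."""
    rng = np.random.default_rng(7)
    starts = [5, 20, 33, 0, 48, 12]
    records = []
    for i, p in enumerate(starts):
        arr = rng.integers(0, 4, size=60)
        seq = "".join("ACGT"[b] for b in arr)
        seq = seq[:p] + "GATTACCA" + seq[p + 8:]
        records.append((f"s{i + 1}", seq))
    return SequenceSet(records), starts, "GATTACCA"


@pytest.fixture
def random_seqs(rng):
    """Ten random 80-bp sequences with no planted structure."""
    records = [
        (f"r{i}", "".join("ACGT"[b] for b in rng.integers(0, 4, size=80)))
        for i in range(10)
    ]
    return SequenceSet(records)
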