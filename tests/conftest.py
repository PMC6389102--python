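import numpy as np
import pytest

import hapmec as hm


@pytest.fixture
def matrix_a() -> hm.ReadMatrix:
    """The six-read worked-example matrix."""
    return hm.example_matrix()


@pytest.fixture
def pair_a() -> hm.HaplotypePair:
    """One optimal complementary pair for the worked-example matrix."""
    return hm.HaplotypePair.complementary("101010")


def random_corpus(seed: int, n: int, max_rows: int = 8, max_cols: int = 10,
                  gap_prob: float = 0.3, error_rate: float = 0.1):
    """Seeded stream of small random fragment matrices."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        p = int(rng.integers(2, max_rows + 1))
        q = int(rng.integers(2, max_cols + 1))
        out.append(hm.random_matrix(rng, p, q, gap_prob, error_rate))
    return out
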