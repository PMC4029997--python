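import numpy as np
import pytest

from adaptrex.ladder import TemperatureLadder, VisitHistogram, geometric_ladder
from adaptrex.models import ideal_helix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def bench_ladder():
    """16 clients spanning 275-350 K, the benchmark run configuration."""
    return geometric_ladder(275.0, 350.0, 16)


@pytest.fixture
def helix():
    return ideal_helix(20)


def linear_index_histogram(ladder: TemperatureLadder, per_gap: int = 100) -> VisitHistogram:
    """Histogram whose fraction-cold profile is exactly linear in window index."""
    n = ladder.n
    total = per_gap * (n - 1)  # divisible by n-1, so fractions are exact
    n_cold = np.array(
        [total - per_gap * i for i in range(n)], dtype=np.int64
    )
    return VisitHistogram(temps=ladder.temps.copy(), n_cold=n_cold,
                          n_hot=total - n_cold)
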