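import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kernel_hotspots import GenomeBuild, GenomicInterval

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def build():
    return GenomeBuild()


@pytest.fixture
def toy_build():
    """A tiny two-chromosome genome for hand-constructed cases."""
    return GenomeBuild("toy", {"chr1": 1_000_000, "chr2": 2_000_000})


def random_intervals(rng: np.random.Generator, n: int, chroms=("1", "2"),
                     max_pos: int = 10_000) -> list[GenomicInterval]:
    """Random valid closed intervals for oracle comparisons."""
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        a, b = sorted(rng.integers(1, max_pos + 1, size=2))
        out.append(GenomicInterval(str(chrom), int(a), int(b)))
    return out
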