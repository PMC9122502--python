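import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from sdmal.hapio import HaplotypeMatrix  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_925)


def make_matrix(alleles, positions=None, chrom="2R", depth=None, group=""):
    """Build a HaplotypeMatrix from a nested list (samples x sites)."""
    alleles = np.asarray(alleles, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, alleles.shape[1] + 1) * 100
    return HaplotypeMatrix(
        chrom=chrom,
        positions=np.asarray(positions),
        samples=[f"s{i}" for i in range(alleles.shape[0])],
        alleles=alleles,
        depth=depth,
        group=group,
    )


@pytest.fixture
def random_matrix(rng):
    """9 x 200 matrix with some missing calls and depth, for filter tests."""
    alleles = rng.integers(0, 2, size=(9, 200)).astype(np.int8)
    miss = rng.random((9, 200)) < 0.05
    # keep at least one call per site
    miss[0] = False
    alleles[miss] = -1
    depth = rng.integers(2, 30, size=(9, 200)).astype(np.int32)
    positions = np.sort(rng.choice(np.arange(1, 100_000), size=200, replace=False))
    return make_matrix(alleles, positions=positions, depth=depth)
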