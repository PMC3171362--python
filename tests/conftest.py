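import numpy as np
import pytest

from cpcm import Partition, ProbeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def step_series():
    """60 unit-spaced probes with an obvious mean step after probe 30."""
    rng = np.random.default_rng(1)
    ratios = np.concatenate(
        [rng.normal(0.0, 0.15, 30), rng.normal(0.7, 0.15, 30)]
    )
    return ProbeSeries(chrom="chr1", positions=np.arange(1.0, 61.0), ratios=ratios)


@pytest.fixture
def flat_series():
    """60 unit-spaced probes with no change."""
    rng = np.random.default_rng(2)
    return ProbeSeries(
        chrom="chr1", positions=np.arange(1.0, 61.0), ratios=rng.normal(0, 0.15, 60)
    )


@pytest.fixture
def two_change_series():
    """60 unit-spaced probes stepping 0 -> 0.7 -> 0 after probes 20 and 40."""
    rng = np.random.default_rng(3)
    ratios = np.concatenate(
        [
            rng.normal(0.0, 0.15, 20),
            rng.normal(0.7, 0.15, 20),
            rng.normal(0.0, 0.15, 20),
        ]
    )
    return ProbeSeries(chrom="chr1", positions=np.arange(1.0, 61.0), ratios=ratios)


def unit_partition(ratios, bin_length: float = 1.0) -> Partition:
    """Partition with exactly one observation per subinterval of equal length.

    Used where a test needs the Poisson count evidence to be flat across
    candidates (equal t_i and equal N_i) rather than the half-length end
    bins that midpoint edges produce.
    """
    ratios = np.asarray(ratios, dtype=float)
    n = ratios.size
    return Partition(
        edges=np.arange(0.0, n + 1.0) * bin_length,
        counts=np.ones(n, dtype=int),
        obs=tuple(ratios[i : i + 1] for i in range(n)),
    )


def raw_partition(edges, counts, obs) -> Partition:
    """Construct a Partition bypassing validation (for edge-case unit tests
    that deliberately relax the >= 1 observations-per-bin rule)."""
    p = object.__new__(Partition)
    object.__setattr__(p, "edges", np.asarray(edges, dtype=float))
    object.__setattr__(p, "counts", np.asarray(counts, dtype=int))
    object.__setattr__(p, "obs", tuple(np.asarray(o, dtype=float) for o in obs))
    return p
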