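"""Marginal posterior of the change subinterval.

The model: probes occur along the chromosome as a homogeneous Poisson
process; the log2 ratio of probe j is Gaussian with mean mu1 (variance
sigma^2) up to an unknown change subinterval k and mean mun after it,
and the probe occurrence rate may likewise change from lam_pre to
lam_post.  With a flat prior on k and on the two means, and the Jeffreys
prior 1/sigma^2 on the common variance, the means and variance integrate
out in closed form.  Writing m for the number of observations through
subinterval k, M for the total,

    A = sum_j x_j^2,  B = sum_{j<=m} x_j,  C = sum_{j>m} x_j,

the Gaussian evidence for candidate k is proportional to

    [m (M - m)]^{-1/2} * (A - B^2/m - C^2/(M - m))^{-(M-2)/2},

and the full weight multiplies in the probability of the observed bin
counts N_i under Poisson rates at their segment MLEs.  The posterior over
candidates k = 2..n-1 is the normalised weight; its argmax is the MAP
change subinterval.  The closed form is validated against direct
numerical integration in :mod:`cpcm.oracle`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .exceptions import DegeneratePartitionError, NoValidCandidateError
from .partition import Partition, assignment_index
from .probe_io import ProbeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentStats",
    "RatePair",
    "ChangePosterior",
    "segment_statistics",
    "gaussian_log_marginal",
    "poisson_rate_mles",
    "poisson_log_prob",
    "change_posterior",
    "estimate_change",
    "change_index_to_position",
]

# relative tolerance below which the residual sum of squares is treated as
# zero (piecewise-constant data; the flat-prior marginal diverges)
_RESIDUAL_RTOL = 1e-12


@dataclass(frozen=True)
class SegmentStats:
    """Sufficient statistics of the two-segment Gaussian likelihood."""

    A: float
    B: float
    C: float
    m: int
    M: int


@dataclass(frozen=True)
class RatePair:
    """Poisson occurrence-rate MLEs before/after the candidate change (1/kb).

    In the three-regime variant ``lam_mid`` holds the rate of the change
    subinterval itself; it is ``None`` in the default two-regime model.
    """

    lam_pre: float
    lam_post: float
    lam_mid: float | None = None


@dataclass(frozen=True)
class ChangePosterior:
    """Normalised posterior p(k | data) over candidate change subintervals.

    ``k_values`` are the candidates 2..n-1 (1-based subinterval indices);
    ``log_weights`` the unnormalised log weights (-inf for excluded
    candidates); ``probs`` the normalised posterior; ``k_hat`` the MAP
    (smallest k on ties) and ``max_prob`` its posterior probability.
    """

    k_values: np.ndarray
    log_weights: np.ndarray
    probs: np.ndarray
    k_hat: int
    max_prob: float


def segment_statistics(x, m: int) -> SegmentStats:
    """Compute A = sum x^2, B = sum of the first m, C = sum of the rest.

    Raises
    ------
    IndexError
        If ``m`` is not in [1, M-1].
    """
    x = np.asarray(x, dtype=float)
    M = x.size
    if not 1 <= m < M:
        raise IndexError(f"m must be in [1, {M - 1}], got {m}")
    return SegmentStats(
        A=float(np.dot(x, x)),
        B=float(x[:m].sum()),
        C=float(x[m:].sum()),
        m=int(m),
        M=int(M),
    )


def gaussian_log_marginal(stats: SegmentStats) -> float:
    """Log Gaussian evidence for a split after observation m (up to a constant).

    Returns ``-inf`` (candidate excluded) when either segment has fewer
    than 2 observations — the flat-prior marginal is not integrable there —
    or when the residual sum of squares vanishes (piecewise-constant data).
    Adding a constant to every observation, or rescaling them, shifts the
    value by an amount independent of m, so the posterior over candidates
    is invariant under affine transforms of the ratios.
    """
    m, M = stats.m, stats.M
    if m < 2 or M - m < 2:
        logger.debug("candidate split m=%d of M=%d excluded (integrability)", m, M)
        return float("-inf")
    resid = stats.A - stats.B**2 / m - stats.C**2 / (M - m)
    if resid <= _RESIDUAL_RTOL * max(stats.A, 1.0):
        logger.warning(
            "residual sum of squares ~0 at m=%d (piecewise-constant data); "
            "candidate excluded", m,
        )
        return float("-inf")
    return -0.5 * np.log(m * (M - m)) - 0.5 * (M - 2) * np.log(resid)


def poisson_rate_mles(
    partition: Partition, k: int, rate_regimes: int = 2
) -> RatePair:
    """Segment Poisson-rate MLEs for candidate change subinterval k.

    Two-regime (default): ``lam_pre`` pools subintervals 1..k and
    ``lam_post`` pools k+1..n, each rate being total count over total
    length.  Three-regime: subinterval k gets its own rate ``lam_mid``,
    with ``lam_pre`` pooling 1..k-1 and ``lam_post`` pooling k+1..n.

    Raises
    ------
    IndexError
        If k is outside 2..n-1.
    DegeneratePartitionError
        If either side has zero genomic length.
    """
    if not 2 <= k <= partition.n - 1:
        raise IndexError(f"k must be in [2, {partition.n - 1}], got {k}")
    counts = partition.counts
    lengths = partition.lengths
    if rate_regimes == 2:
        t_pre = lengths[:k].sum()
        t_post = lengths[k:].sum()
        if t_pre <= 0 or t_post <= 0:
            raise DegeneratePartitionError(f"zero genomic length on one side of k={k}")
        return RatePair(
            lam_pre=float(counts[:k].sum() / t_pre),
            lam_post=float(counts[k:].sum() / t_post),
        )
    if rate_regimes == 3:
        t_pre = lengths[: k - 1].sum()
        t_mid = lengths[k - 1]
        t_post = lengths[k:].sum()
        if t_pre <= 0 or t_mid <= 0 or t_post <= 0:
            raise DegeneratePartitionError(f"zero genomic length in a regime at k={k}")
        return RatePair(
            lam_pre=float(counts[: k - 1].sum() / t_pre),
            lam_post=float(counts[k:].sum() / t_post),
            lam_mid=float(counts[k - 1] / t_mid),
        )
    raise ValueError(f"rate_regimes must be 2 or 3, got {rate_regimes}")


def _pois_logpmf(n: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Poisson log pmf with the convention Pois(0; 0) = 1.

    A zero mean with a positive count yields -inf (impossible
    configuration), never an exception.
    """
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = np.full(np.broadcast_shapes(n.shape, mu.shape), -np.inf)
    pos = mu > 0
    out = np.where(pos, np.where(pos, n, 0.0) * np.log(np.where(pos, mu, 1.0))
                   - mu - gammaln(n + 1), out)
    out = np.where((mu == 0) & (n == 0), 0.0, out)
    return out


def poisson_log_prob(partition: Partition, k: int, rates: RatePair) -> float:
    """Log probability of the observed bin counts under the segment rates.

    Sum over subintervals of log Pois(N_i; lam * t_i), with lam = lam_pre
    for i <= k and lam_post for i > k (the three-regime variant inserts
    lam_mid at i = k).
    """
    counts = partition.counts
    lengths = partition.lengths
    if rates.lam_mid is None:
        mu = np.concatenate(
            [rates.lam_pre * lengths[:k], rates.lam_post * lengths[k:]]
        )
    else:
        mu = np.concatenate(
            [
                rates.lam_pre * lengths[: k - 1],
                [rates.lam_mid * lengths[k - 1]],
                rates.lam_post * lengths[k:],
            ]
        )
    return float(_pois_logpmf(counts, mu).sum())


def change_posterior(partition: Partition, rate_regimes: int = 2) -> ChangePosterior:
    """Normalised posterior of the change subinterval over k = 2..n-1.

    For each candidate k the log weight is the Gaussian evidence of the
    observation split after subinterval k plus the Poisson log probability
    of the bin counts at their segment rate MLEs; a flat prior on k makes
    the posterior a softmax of the log weights.  Candidates whose split
    leaves fewer than 2 observations on a side carry probability 0.

    Raises
    ------
    NoValidCandidateError
        If every candidate is excluded (needs n >= 4 and enough
        observations on both flanks).
    """
    n = partition.n
    if n < 4:
        raise NoValidCandidateError(f"need at least 4 subintervals, got {n}")
    x = partition.all_ratios
    k_values = np.arange(2, n)
    log_weights = np.empty(k_values.size)
    n_excluded = 0
    for i, k in enumerate(k_values):
        m, M = assignment_index(partition, int(k))
        if m < 2 or M - m < 2:
            log_weights[i] = -np.inf
            n_excluded += 1
            continue
        lw = gaussian_log_marginal(segment_statistics(x, m))
        if np.isfinite(lw):
            rates = poisson_rate_mles(partition, int(k), rate_regimes)
            lw += poisson_log_prob(partition, int(k), rates)
        log_weights[i] = lw
    if n_excluded:
        logger.info("%d of %d candidates excluded (too few flank observations)",
                    n_excluded, k_values.size)
    finite = np.isfinite(log_weights)
    if not finite.any():
        raise NoValidCandidateError("all candidate change subintervals excluded")
    shifted = log_weights - log_weights[finite].max()
    w = np.where(finite, np.exp(np.where(finite, shifted, -np.inf)), 0.0)
    probs = w / w.sum()
    i_hat = int(np.argmax(probs))  # argmax returns the first (smallest k) on ties
    return ChangePosterior(
        k_values=k_values,
        log_weights=log_weights,
        probs=probs,
        k_hat=int(k_values[i_hat]),
        max_prob=float(probs[i_hat]),
    )


def estimate_change(
    cp: ChangePosterior, threshold: float = 0.5
) -> tuple[int, float] | None:
    """Declare the MAP change subinterval if its posterior clears the threshold.

    Returns ``(k_hat, max_prob)`` when ``max_prob > threshold``, else
    ``None`` (no change declared).  ``threshold`` defaults to the heuristic
    0.5; 0 gives the pure MAP estimator.  Ties are already broken toward
    the smallest k in :func:`change_posterior`.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if cp.max_prob > threshold:
        return cp.k_hat, cp.max_prob
    return None


def change_index_to_position(
    partition: Partition, ps: ProbeSeries, k_hat: int
) -> float:
    """Convert a change subinterval index into a genomic locus tau (kb).

    The declared locus is the position of the last probe contained in
    subinterval ``k_hat``: the segment up to and including that probe is
    the pre-change regime.

    Raises
    ------
    IndexError
        If k_hat is outside 2..n-1.
    """
    if not 2 <= k_hat <= partition.n - 1:
        raise IndexError(f"k_hat must be in [2, {partition.n - 1}], got {k_hat}")
    if partition.total_count != ps.n_probes:
        raise ValueError("partition does not match the probe series")
    last_idx = int(partition.cum_counts[k_hat - 1]) - 1
    return float(ps.positions[last_idx])
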