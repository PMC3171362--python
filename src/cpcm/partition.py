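"""Division of a chromosome into non-overlapping subintervals.

The change-point model works on n subintervals with genomic lengths t_i
and biomarker counts N_i.  Binning honours the rule that every
subinterval holds at least 1 and at most 300 observations, in either
equal-width (equal t_i) or equal-count (equal N_i up to 1) mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConstraintViolationError, InvalidInputError
from .probe_io import ProbeSeries

__all__ = ["Partition", "make_partition", "assignment_index", "MAX_OBS_PER_BIN"]

MAX_OBS_PER_BIN = 300


@dataclass(frozen=True)
class Partition:
    """n subintervals with edges, lengths t_i, counts N_i and member ratios.

    ``edges`` has n+1 increasing coordinates (kb) spanning the probe
    range; ``obs[i]`` holds the ordered log ratios of subinterval i+1.
    Subinterval indices are 1-based throughout the public API, matching
    the change-point candidate range k = 2..n-1.
    """

    edges: np.ndarray
    counts: np.ndarray
    obs: tuple

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "obs", tuple(np.asarray(o, dtype=float) for o in self.obs))
        if edges.ndim != 1 or edges.size != counts.size + 1:
            raise InvalidInputError("edges must have one more entry than counts")
        if np.any(np.diff(edges) <= 0):
            raise InvalidInputError("edges must be strictly increasing (positive lengths)")
        if len(self.obs) != counts.size:
            raise InvalidInputError("obs must have one entry per subinterval")
        if any(len(o) != c for o, c in zip(self.obs, counts)):
            raise InvalidInputError("obs lengths must match counts")
        if np.any(counts < 1) or np.any(counts > MAX_OBS_PER_BIN):
            raise ConstraintViolationError(
                f"each subinterval must contain between 1 and {MAX_OBS_PER_BIN} "
                f"observations; got counts in [{counts.min()}, {counts.max()}]"
            )

    @property
    def n(self) -> int:
        """Number of subintervals."""
        return int(self.counts.size)

    @property
    def lengths(self) -> np.ndarray:
        """Subinterval lengths t_i in kb."""
        return np.diff(self.edges)

    @property
    def cum_counts(self) -> np.ndarray:
        """Running totals of N_i; the last entry is M."""
        return np.cumsum(self.counts)

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    @property
    def all_ratios(self) -> np.ndarray:
        """All member log ratios in genomic order."""
        return np.concatenate(self.obs)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (bin index, start_kb, end_kb, count) for inspection."""
        return pd.DataFrame(
            {
                "bin": np.arange(1, self.n + 1),
                "start_kb": self.edges[:-1],
                "end_kb": self.edges[1:],
                "count": self.counts,
            }
        )


def _equal_count_partition(ps: ProbeSeries, n_bins: int) -> Partition:
    m, r = divmod(ps.n_probes, n_bins)
    counts = np.full(n_bins, m, dtype=int)
    counts[:r] += 1  # counts differ by at most 1; surplus goes to leading bins
    cum = np.concatenate([[0], np.cumsum(counts)])
    # interior edges at the midpoint between the bounding probes so that
    # t_i reflects true genomic extent
    inner = 0.5 * (ps.positions[cum[1:-1] - 1] + ps.positions[cum[1:-1]])
    edges = np.concatenate([[ps.positions[0]], inner, [ps.positions[-1]]])
    obs = tuple(ps.ratios[cum[i]:cum[i + 1]] for i in range(n_bins))
    return Partition(edges=edges, counts=counts, obs=obs)


def _equal_width_partition(ps: ProbeSeries, n_bins: int) -> Partition:
    edges = np.linspace(ps.positions[0], ps.positions[-1], n_bins + 1)
    # half-open [edge_{i-1}, edge_i), final bin closed on the right
    idx = np.minimum(np.searchsorted(edges, ps.positions, side="right") - 1, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        empty = int(np.argmax(counts == 0)) + 1
        raise ConstraintViolationError(
            f"equal-width binning leaves subinterval {empty} empty; "
            f"lower n_bins or use equal-count mode"
        )
    cum = np.concatenate([[0], np.cumsum(counts)])
    obs = tuple(ps.ratios[cum[i]:cum[i + 1]] for i in range(n_bins))
    return Partition(edges=edges, counts=counts, obs=obs)


def make_partition(ps: ProbeSeries, n_bins: int, mode: str = "equal-count") -> Partition:
    """Partition a probe series into ``n_bins`` subintervals.

    Parameters
    ----------
    ps
        Probe series sorted by position.
    n_bins
        Number of subintervals; must satisfy ``3 <= n_bins <= ps.n_probes``
        (the change search needs candidates k in 2..n-1).
    mode
        ``"equal-count"``: counts differ by at most 1 and interior edges sit
        at midpoints between the bounding probes.  ``"equal-width"``: all
        lengths equal; raises if any bin ends up empty.

    Raises
    ------
    InvalidInputError
        If ``n_bins`` is out of range or the mode is unknown.
    ConstraintViolationError
        If a bin is empty (equal-width) or any bin exceeds 300 observations.
    """
    if not 3 <= n_bins <= ps.n_probes:
        raise InvalidInputError(
            f"n_bins must be in [3, n_probes={ps.n_probes}], got {n_bins}"
        )
    if mode == "equal-count":
        return _equal_count_partition(ps, n_bins)
    if mode == "equal-width":
        return _equal_width_partition(ps, n_bins)
    raise InvalidInputError(f"mode must be 'equal-count' or 'equal-width', got {mode!r}")


def default_n_bins(n_probes: int) -> int:
    """Default number of subintervals: ~10 observations per bin.

    ``floor(n_probes / 10)`` clipped to [3, n_probes], keeping counts well
    inside the 1..300 rule while leaving the per-bin Gaussian evidence
    informative.
    """
    return int(np.clip(n_probes // 10, 3, n_probes))


def assignment_index(partition: Partition, k: int) -> tuple[int, int]:
    """Observation split implied by candidate change subinterval k.

    Returns ``(m, M)`` where m is the number of observations through
    subinterval k (1-based) and M the total.

    Raises
    ------
    IndexError
        If k is outside 2..n-1.
    """
    if not 2 <= k <= partition.n - 1:
        raise IndexError(f"k must be in [2, {partition.n - 1}], got {k}")
    cum = partition.cum_counts
    return int(cum[k - 1]), int(cum[-1])
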