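"""Sliding-window scan for multiple change loci on a chromosome.

A chromosome with several copy-number aberrations is scanned with
overlapping windows of subintervals (recommended sizes 12-35); each
window is analysed with the single-change posterior, and windows whose
maximum posterior clears the threshold declare a call at the position of
the last probe of the pre-change segment.  Calls that overlapping
windows re-detect within one subinterval are merged, keeping the higher
posterior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import NoValidCandidateError
from .partition import Partition, default_n_bins, make_partition
from .posterior import change_index_to_position, change_posterior, estimate_change
from .probe_io import ProbeSeries

logger = logging.getLogger(__name__)

__all__ = ["WindowPlan", "CNVCall", "plan_windows", "subpartition", "scan",
           "calls_to_frame", "calls_to_bed"]

RECOMMENDED_WINDOW_RANGE = (12, 35)


@dataclass(frozen=True)
class WindowPlan:
    """Ordered overlapping windows of subinterval indices (1-based, inclusive)."""

    windows: tuple
    window_size: int
    overlap_frac: float

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass(frozen=True)
class CNVCall:
    """A declared copy-number change locus."""

    chrom: str
    tau_kb: float
    posterior: float
    window_id: int
    k_global: int


def plan_windows(n_bins: int, window_size: int = 20, overlap_frac: float = 0.5) -> WindowPlan:
    """Place overlapping windows of ``window_size`` subintervals over ``n_bins``.

    Consecutive windows advance by ``max(1, round(window_size * (1 -
    overlap_frac)))`` subintervals; the last window is end-aligned so the
    whole range is covered.  If ``n_bins < window_size`` a single window
    covering everything is returned with a logged note.
    """
    if window_size < 4:
        raise ValueError(f"window_size must be >= 4, got {window_size}")
    if not 0 < overlap_frac < 1:
        raise ValueError(f"overlap_frac must be in (0, 1), got {overlap_frac}")
    lo, hi = RECOMMENDED_WINDOW_RANGE
    if not lo <= window_size <= hi:
        logger.warning(
            "window_size %d outside the recommended %d-%d subintervals",
            window_size, lo, hi,
        )
    if n_bins < window_size:
        logger.info(
            "n_bins=%d smaller than window_size=%d: using one window", n_bins, window_size
        )
        return WindowPlan(windows=((1, n_bins),), window_size=window_size,
                          overlap_frac=overlap_frac)
    # step capped at window_size - 1 so neighbours always share a subinterval
    step = min(window_size - 1, max(1, round(window_size * (1 - overlap_frac))))
    starts = list(range(1, n_bins - window_size + 1, step)) or [1]
    if starts[-1] + window_size - 1 < n_bins:
        starts.append(n_bins - window_size + 1)  # end-align the final window
    windows = tuple((s, s + window_size - 1) for s in starts)
    return WindowPlan(windows=windows, window_size=window_size, overlap_frac=overlap_frac)


def subpartition(partition: Partition, first: int, last: int) -> Partition:
    """The partition restricted to subintervals ``first..last`` (1-based, inclusive)."""
    if not 1 <= first <= last <= partition.n:
        raise IndexError(f"window [{first}, {last}] out of range 1..{partition.n}")
    return Partition(
        edges=partition.edges[first - 1 : last + 1],
        counts=partition.counts[first - 1 : last],
        obs=partition.obs[first - 1 : last],
    )


def scan(
    ps: ProbeSeries,
    n_bins: int | None = None,
    *,
    mode: str = "equal-count",
    window_size: int = 20,
    overlap_frac: float = 0.5,
    threshold: float = 0.5,
    rate_regimes: int = 2,
) -> list[CNVCall]:
    """Detect change loci with the sliding-window posterior scan.

    Parameters
    ----------
    ps
        Probe series of one chromosome.
    n_bins
        Total subintervals; default ~10 observations per bin.
    window_size, overlap_frac
        Window geometry; see :func:`plan_windows`.
    threshold
        Posterior threshold for declaring a call (default heuristic 0.5).

    Returns
    -------
    list of CNVCall sorted by genomic position; calls re-detected by
    overlapping windows within one subinterval are merged, keeping the
    higher posterior.
    """
    if n_bins is None:
        n_bins = default_n_bins(ps.n_probes)
    partition = make_partition(ps, n_bins, mode)
    plan = plan_windows(partition.n, window_size, overlap_frac)

    raw: list[CNVCall] = []
    for wid, (first, last) in enumerate(plan.windows, start=1):
        sub = subpartition(partition, first, last)
        if sub.n < 4:
            logger.info("window %d has %d < 4 subintervals; skipped", wid, sub.n)
            continue
        try:
            cp = change_posterior(sub, rate_regimes=rate_regimes)
        except NoValidCandidateError:
            logger.info("window %d: all candidates excluded; no call", wid)
            continue
        declared = estimate_change(cp, threshold)
        if declared is None:
            logger.info("window %d: max posterior %.4f below threshold; no call",
                        wid, cp.max_prob)
            continue
        k_local, max_prob = declared
        k_global = first + k_local - 1
        tau = float(ps.positions[int(partition.cum_counts[k_global - 1]) - 1])
        logger.info("window %d: call at k=%d (tau=%.1f kb, posterior %.4f)",
                    wid, k_global, tau, max_prob)
        raw.append(CNVCall(chrom=ps.chrom, tau_kb=tau, posterior=max_prob,
                           window_id=wid, k_global=k_global))

    merged: list[CNVCall] = []
    for call in sorted(raw, key=lambda c: (c.k_global, c.window_id)):
        if merged and call.k_global - merged[-1].k_global <= 1:
            if call.posterior > merged[-1].posterior:
                merged[-1] = call
        else:
            merged.append(call)
    return sorted(merged, key=lambda c: c.tau_kb)


def calls_to_frame(calls: list[CNVCall]) -> pd.DataFrame:
    """Tabular view of a call list (chrom, tau_kb, posterior, window_id, k_global)."""
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "tau_kb": c.tau_kb,
                "posterior": c.posterior,
                "window_id": c.window_id,
                "k_global": c.k_global,
            }
            for c in calls
        ],
        columns=["chrom", "tau_kb", "posterior", "window_id", "k_global"],
    )


def calls_to_bed(calls: list[CNVCall]) -> pd.DataFrame:
    """BED view of the calls: 1-bp breakpoint features, 0-based half-open.

    tau is converted kb -> bp; the score column carries the posterior
    scaled by 1000 and capped at 1000.
    """
    rows = []
    for c in calls:
        start = int(round(c.tau_kb * 1000))
        rows.append(
            {
                "chrom": c.chrom,
                "chromStart": start,
                "chromEnd": start + 1,
                "name": f"cnv_breakpoint_w{c.window_id}",
                "score": min(1000, int(round(c.posterior * 1000))),
                "strand": ".",
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "chromStart", "chromEnd",
                                       "name", "score", "strand"])


def stability_sweep(
    ps: ProbeSeries,
    n_bins: int | None = None,
    *,
    window_sizes: tuple = (12, 15, 20, 25, 30, 35),
    min_support: int = 3,
    **scan_kwargs,
) -> list[CNVCall]:
    """Re-run the scan across several window sizes and keep stable calls.

    A call is kept when windows of at least ``min_support`` different
    sizes declare a change within one subinterval of each other; the
    representative with the highest posterior is reported.  This is the
    optional stopping rule for choosing the window size: report only the
    loci on which the posterior stabilises.
    """
    per_size = [scan(ps, n_bins, window_size=w, **scan_kwargs) for w in window_sizes]
    pool = sorted((c for calls in per_size for c in calls), key=lambda c: c.k_global)
    stable: list[CNVCall] = []
    cluster: list[CNVCall] = []
    for call in pool + [None]:
        if call is not None and (not cluster or call.k_global - cluster[-1].k_global <= 1):
            cluster.append(call)
            continue
        if len(cluster) >= min_support:
            stable.append(max(cluster, key=lambda c: c.posterior))
        cluster = [call] if call is not None else []
    return sorted(stable, key=lambda c: c.tau_kb)
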