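"""Cluster-based permutation analysis of condition-vs-unrelated looking.

Per 50-ms bin, a two-sided paired t-test compares participant-level
(trial-averaged) fixation proportions between a condition and the unrelated
distractor.  Runs of two or more adjacent supra-threshold bins of the same
sign form clusters scored by the sum of their t statistics (the Σt cluster
mass).  The permutation null flips each participant's condition/unrelated
labels independently (a sign flip of their difference series — exact for
this paired design), summarizing each permutation by its maximal |Σt|; the
reported p carries the +1 correction so it can never be zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import BinnedFixationTensor

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_N_PERM = 1000
MIN_CLUSTER_BINS = 2


@dataclass
class ClusterResult:
    comparison: str
    group: str
    start_ms: float
    end_ms: float
    bins: list[int]
    sum_t: float
    p: float | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def paired_t_series(diff: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-bin paired t statistics for an (n_participants, n_bins) difference
    matrix; bins with zero within-pair variance yield NaN."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    return t, n - 1


def find_clusters(t: np.ndarray, t_crit: float,
                  min_bins: int = MIN_CLUSTER_BINS) -> list[tuple[list[int], float]]:
    """Maximal runs of >= min_bins adjacent same-sign supra-threshold bins.

    NaN bins (undefined t) break adjacency and never join a cluster.
    """
    clusters = []
    run: list[int] = []
    run_sign = 0

    def close():
        nonlocal run, run_sign
        if len(run) >= min_bins:
            clusters.append((run, float(np.sum(t[run]))))
        run, run_sign = [], 0

    for b, tb in enumerate(t):
        if np.isnan(tb) or abs(tb) <= t_crit:
            close()
            continue
        sign = 1 if tb > 0 else -1
        if run and sign != run_sign:
            close()
        run.append(b)
        run_sign = sign
    close()
    return clusters


def _difference_matrix(tensor: BinnedFixationTensor, comparison: str,
                       group: str) -> np.ndarray:
    sub = tensor.select_group(group)
    props = sub.participant_proportions()
    diff = (props[..., sub.condition_index(comparison)]
            - props[..., sub.condition_index("unrelated")])
    # canonical participant order makes seeded permutations invariant to
    # the order participants arrive in
    return diff[np.argsort(np.asarray(sub.participants, dtype=object))]


def cluster_stats(tensor: BinnedFixationTensor, comparison: str, group: str,
                  alpha: float = DEFAULT_ALPHA
                  ) -> tuple[pd.DataFrame, list[ClusterResult]]:
    """Observed per-bin tests and clusters (without permutation p-values)."""
    diff = _difference_matrix(tensor, comparison, group)
    if diff.shape[0] < 3:
        raise ValueError(f"group {group!r} has fewer than 3 participants")
    t, df = paired_t_series(diff)
    if np.isnan(t).any():
        logger.warning(
            "%s vs unrelated (%s): %d bin(s) with zero within-pair variance "
            "excluded from clustering", comparison, group,
            int(np.isnan(t).sum()))
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    starts = tensor.bin_starts()
    series = pd.DataFrame({
        "bin": np.arange(len(t)), "t_ms": starts, "t": t, "df": df,
        "supra": np.abs(t) > t_crit, "sign": np.sign(t),
    })
    clusters = [
        ClusterResult(comparison, group, float(starts[bins[0]]),
                      float(starts[bins[-1]] + tensor.bin_width), bins, sum_t)
        for bins, sum_t in find_clusters(t, t_crit)
    ]
    return series, clusters


def max_cluster_stat(t_matrix: np.ndarray, t_crit: float,
                     min_bins: int = MIN_CLUSTER_BINS) -> np.ndarray:
    """Max |Σt| over clusters, per row of a (n_perm, n_bins) t matrix."""
    out = np.zeros(t_matrix.shape[0])
    for r, trow in enumerate(t_matrix):
        cl = find_clusters(trow, t_crit, min_bins)
        if cl:
            out[r] = max(abs(s) for _, s in cl)
    return out


def permutation_test(tensor: BinnedFixationTensor, comparison: str,
                     group: str, n_perm: int = DEFAULT_N_PERM,
                     seed: int | None = None, alpha: float = DEFAULT_ALPHA
                     ) -> tuple[pd.DataFrame, list[ClusterResult], np.ndarray]:
    """Attach permutation p-values to the observed clusters.

    Returns (bin test series, clusters with p, null max-|Σt| distribution).
    p = (1 + #{null >= |Σt_obs|}) / (n_perm + 1), two-sided via |Σt|.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    series, clusters = cluster_stats(tensor, comparison, group, alpha)
    diff = _difference_matrix(tensor, comparison, group)
    n, n_bins = diff.shape
    t_crit = stats.t.ppf(1 - alpha / 2, n - 1)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    # sign flips leave |x| fixed: per-bin variance recoverable from sumsq
    sumsq = (diff ** 2).sum(axis=0)                     # (B,)
    means = signs @ diff / n                            # (n_perm, B)
    var = (sumsq - n * means ** 2) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_null = np.where(var > 0, means / np.sqrt(var / n), np.nan)
    null_max = max_cluster_stat(t_null, t_crit)

    for cl in clusters:
        cl.p = float((1 + np.sum(null_max >= abs(cl.sum_t))) / (n_perm + 1))
    return series, clusters, null_max


def clusters_frame(clusters: list[ClusterResult]) -> pd.DataFrame:
    rows = [{"group": c.group, "comparison": c.comparison,
             "start_ms": c.start_ms, "end_ms": c.end_ms,
             "n_bins": c.n_bins, "sum_t": c.sum_t, "p": c.p}
            for c in clusters]
    return pd.DataFrame(rows, columns=["group", "comparison", "start_ms",
                                       "end_ms", "n_bins", "sum_t", "p"])
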