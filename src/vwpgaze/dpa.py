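"""Bootstrap divergence-point analysis.

The divergence point of a group is the onset of sustained target-over-
agent-related looking: per 50-ms bin inside the 750-2500 ms window a
one-sided paired t-test (target > agent-related, on participant-level
trial-averaged proportions) is evaluated, and the onset is the start of the
first run of at least K consecutive significant bins (default K = 4, i.e.
200 ms of sustained divergence).

Bootstrapping resamples participants with replacement within each group
(1000 iterations by default), recomputing the onset per iteration; the
group estimate is the mean of the bootstrap onsets with a 95% percentile
interval.  The group difference is summarized from the paired per-iteration
onset differences, with a proportion-based two-sided p-value
2*min(P(diff<=0), P(diff>=0)) carrying a +1 correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import BinnedFixationTensor

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (750.0, 2500.0)
DEFAULT_RUN_BINS = 4
DEFAULT_ALPHA = 0.05
DEFAULT_N_BOOT = 1000
MISSING_WARN_FRACTION = 0.10


@dataclass
class DivergenceResult:
    group: str
    dp_estimate_ms: float                # mean of the bootstrap onsets
    ci95: tuple[float, float]            # percentile interval
    original_onset_ms: float | None      # onset in the unresampled data
    bootstrap_onsets: np.ndarray         # NaN where an iteration had none
    n_missing: int
    settings: dict = field(default_factory=dict)


@dataclass
class GroupDifference:
    difference_ms: float                 # mean over paired bootstrap draws
    ci95: tuple[float, float]
    p: float
    bootstrap_differences: np.ndarray
    n_missing: int
    order: tuple[str, str]               # difference = order[1] - order[0]


def _onset_from_sig(sig: np.ndarray, starts: np.ndarray,
                    run_bins: int) -> float:
    """Start time of the first run of >= run_bins consecutive True; NaN if
    none.  ``sig`` may be 1-D or 2-D (rows = bootstrap iterations)."""
    sig = np.atleast_2d(sig)
    n_iter, n_bins = sig.shape
    out = np.full(n_iter, np.nan)
    run = np.zeros(n_iter, dtype=int)
    done = np.zeros(n_iter, dtype=bool)
    for b in range(n_bins):
        run = np.where(sig[:, b], run + 1, 0)
        hit = (~done) & (run >= run_bins)
        out[hit] = starts[b - run_bins + 1]
        done |= hit
    return out if out.size > 1 else float(out[0])


def _window_diffs(tensor: BinnedFixationTensor, group: str,
                  window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    if window[0] < tensor.window[0] or window[1] > tensor.window[1]:
        raise ValueError(f"analysis window {window} outside tensor window "
                         f"{tensor.window}")
    sub = tensor.select_group(group)
    props = sub.participant_proportions()
    diff = (props[..., sub.condition_index("target")]
            - props[..., sub.condition_index("agent_related")])
    # canonical participant order: seeded bootstraps are then invariant to
    # the order participants arrive in
    diff = diff[np.argsort(np.asarray(sub.participants, dtype=object))]
    starts = tensor.bin_starts()
    keep = (starts >= window[0]) & (starts < window[1])
    return diff[:, keep], starts[keep]


def _sig_matrix(diff: np.ndarray, alpha: float) -> np.ndarray:
    """One-sided significance (target > agent-related) per bin.

    ``diff`` is (..., n_participants, n_bins); the test runs across the
    participant axis.
    """
    n = diff.shape[-2]
    t_crit = stats.t.ppf(1 - alpha, n - 1)
    mean = diff.mean(axis=-2)
    sd = diff.std(axis=-2, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.inf * np.sign(mean))
    t = np.where((sd == 0) & (mean == 0), -np.inf, t)
    return t > t_crit


def onset_from_curves(tensor: BinnedFixationTensor, group: str,
                      window: tuple[float, float] = DEFAULT_WINDOW,
                      run_bins: int = DEFAULT_RUN_BINS,
                      alpha: float = DEFAULT_ALPHA) -> float | None:
    """Divergence onset (ms) for one group, or None if never sustained."""
    diff, starts = _window_diffs(tensor, group, window)
    if diff.shape[0] < 3:
        raise ValueError(f"group {group!r} has fewer than 3 participants")
    onset = _onset_from_sig(_sig_matrix(diff, alpha), starts, run_bins)
    return None if np.isnan(onset) else float(onset)


def bootstrap_divergence(tensor: BinnedFixationTensor,
                         groups: tuple[str, str] = ("autistic", "NT"),
                         n_boot: int = DEFAULT_N_BOOT,
                         seed: int | None = None,
                         window: tuple[float, float] = DEFAULT_WINDOW,
                         run_bins: int = DEFAULT_RUN_BINS,
                         alpha: float = DEFAULT_ALPHA
                         ) -> tuple[dict[str, DivergenceResult], GroupDifference]:
    """Per-group bootstrap divergence estimates and their difference.

    The difference is ``onset(groups[1]) - onset(groups[0])`` per paired
    bootstrap iteration: with the default order, negative values mean the
    NT group diverges earlier than the autistic group.
    """
    rng = np.random.default_rng(seed)
    settings = {"window": window, "run_bins": run_bins, "alpha": alpha,
                "n_boot": n_boot, "test": "one-sided paired t",
                "resampling": "participants within group"}
    results: dict[str, DivergenceResult] = {}
    boot_onsets = {}
    for group in groups:
        diff, starts = _window_diffs(tensor, group, window)
        n = diff.shape[0]
        if n < 3:
            raise ValueError(f"group {group!r} has fewer than 3 participants")
        original = _onset_from_sig(_sig_matrix(diff, alpha), starts, run_bins)
        idx = rng.integers(0, n, size=(n_boot, n))
        sig = _sig_matrix(diff[idx], alpha)            # (n_boot, n_bins)
        onsets = _onset_from_sig(sig, starts, run_bins)
        onsets = np.atleast_1d(onsets)
        n_missing = int(np.isnan(onsets).sum())
        if n_missing > MISSING_WARN_FRACTION * n_boot:
            logger.warning(
                "group %s: %d/%d bootstrap iterations had no sustained "
                "divergence; estimates may be unstable", group, n_missing,
                n_boot)
        valid = onsets[~np.isnan(onsets)]
        est = float(valid.mean()) if valid.size else np.nan
        ci = (tuple(np.percentile(valid, [2.5, 97.5])) if valid.size
              else (np.nan, np.nan))
        results[group] = DivergenceResult(
            group, est, (float(ci[0]), float(ci[1])),
            None if np.isnan(np.atleast_1d(original)[0]) else float(original),
            onsets, n_missing, dict(settings))
        boot_onsets[group] = onsets

    diffs = boot_onsets[groups[1]] - boot_onsets[groups[0]]
    valid = diffs[~np.isnan(diffs)]
    m = valid.size
    n_missing = int(n_boot - m)
    if m == 0:
        difference = GroupDifference(np.nan, (np.nan, np.nan), np.nan,
                                     diffs, n_missing, tuple(groups))
    else:
        p_lo = (1 + np.sum(valid <= 0)) / (m + 1)
        p_hi = (1 + np.sum(valid >= 0)) / (m + 1)
        p = float(min(1.0, 2 * min(p_lo, p_hi)))
        ci = np.percentile(valid, [2.5, 97.5])
        difference = GroupDifference(float(valid.mean()),
                                     (float(ci[0]), float(ci[1])), p, diffs,
                                     n_missing, tuple(groups))
    if n_missing > MISSING_WARN_FRACTION * n_boot:
        logger.warning(
            "group difference: %d/%d bootstrap iterations missing an onset",
            n_missing, n_boot)
    return results, difference


def divergence_frame(results: dict[str, DivergenceResult]) -> pd.DataFrame:
    rows = [{"group": r.group, "dp_estimate_ms": r.dp_estimate_ms,
             "ci_lo_ms": r.ci95[0], "ci_hi_ms": r.ci95[1],
             "original_onset_ms": (np.nan if r.original_onset_ms is None
                                   else r.original_onset_ms),
             "n_missing": r.n_missing}
            for r in results.values()]
    return pd.DataFrame(rows, columns=["group", "dp_estimate_ms", "ci_lo_ms",
                                       "ci_hi_ms", "original_onset_ms",
                                       "n_missing"])
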