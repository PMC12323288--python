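"""Fixation-proportion curves, log-gaze proportion ratios and
per-participant prediction-efficiency indices.

The log-gaze proportion ratio is

    log((fixation on target + 0.5) / (fixation on unrelated + 0.5))

computed per 50-ms bin with the natural logarithm; the +0.5 offsets keep
the ratio finite for binary occupancies.  Positive values index predictive
bias toward the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import BinnedFixationTensor

#: Prediction window: agent onset to patient onset (bins fully inside).
PREDICTION_WINDOW_MS = (0.0, 1300.0)
#: Individual divergence points are searched from verb onset onward.
DP_SEARCH_WINDOW_MS = (750.0, 2500.0)
#: Sustained-run criterion for individual divergence points (bins).
DEFAULT_RUN_BINS = 4


def proportion_curves(tensor: BinnedFixationTensor,
                      groups: list[str] | None = None,
                      ci: float = 0.95) -> pd.DataFrame:
    """Mean fixation proportion per (group, condition, bin) with normal CIs.

    Proportions are trial means within participant, then participant means
    within group; the CI reflects across-participant variability.
    """
    groups = groups if groups is not None else sorted(set(tensor.groups))
    z = stats.norm.ppf(0.5 + ci / 2)
    props = tensor.participant_proportions()          # (P, B, C)
    t_ms = tensor.bin_starts()
    rows = []
    for group in groups:
        mask = tensor.group_mask(group)
        sub = props[mask]                             # (n, B, C)
        n = mask.sum()
        mean = sub.mean(axis=0)
        se = sub.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
        for ci_, cond in enumerate(tensor.conditions):
            rows.append(pd.DataFrame({
                "group": group, "condition": cond,
                "bin": np.arange(tensor.n_bins), "t_ms": t_ms,
                "mean": mean[:, ci_],
                "ci_lo": mean[:, ci_] - z * se[:, ci_],
                "ci_hi": mean[:, ci_] + z * se[:, ci_],
                "n": int(n),
            }))
    return pd.concat(rows, ignore_index=True)


def log_ratio(target_occ, unrelated_occ):
    """The log-gaze proportion ratio.

    Computed as log(t + 0.5) - log(u + 0.5) — mathematically the log of the
    ratio, and bitwise antisymmetric under swapping the arguments.
    """
    return (np.log(np.asarray(target_occ, float) + 0.5)
            - np.log(np.asarray(unrelated_occ, float) + 0.5))


@dataclass
class LogRatioSeries:
    """Log-gaze proportion ratios at trial or participant level."""

    frame: pd.DataFrame          # participant_id, group, [trial_id], bin, t_ms, log_ratio
    level: str                   # "trial" | "participant"
    bin_width: float = 50.0

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "LogRatioSeries":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        return cls(df, "trial" if "trial_id" in df.columns else "participant")


def log_ratio_series(tensor: BinnedFixationTensor,
                     level: str = "trial") -> LogRatioSeries:
    """Compute the log-ratio series from the binned tensor.

    ``level="trial"`` applies the formula to the binary per-trial
    occupancies (the default: the growth model has random intercepts for
    both participants and trials); ``level="participant"`` applies it to
    across-trial proportions.
    """
    it = tensor.condition_index("target")
    iu = tensor.condition_index("unrelated")
    t_ms = tensor.bin_starts()
    if level == "trial":
        vals = log_ratio(tensor.data[..., it], tensor.data[..., iu])  # (P,T,B)
        p, t, b = vals.shape
        idx = np.indices((p, t, b)).reshape(3, -1)
        frame = pd.DataFrame({
            "participant_id": np.asarray(tensor.participants, object)[idx[0]],
            "group": tensor.groups[idx[0]],
            "trial_id": np.asarray(tensor.trials, object)[idx[1]],
            "bin": idx[2], "t_ms": t_ms[idx[2]],
            "log_ratio": vals.reshape(-1),
        })
    elif level == "participant":
        props = tensor.participant_proportions()
        vals = log_ratio(props[..., it], props[..., iu])              # (P,B)
        p, b = vals.shape
        idx = np.indices((p, b)).reshape(2, -1)
        frame = pd.DataFrame({
            "participant_id": np.asarray(tensor.participants, object)[idx[0]],
            "group": tensor.groups[idx[0]],
            "bin": idx[1], "t_ms": t_ms[idx[1]],
            "log_ratio": vals.reshape(-1),
        })
    else:
        raise ValueError("level must be 'trial' or 'participant'")
    return LogRatioSeries(frame, level, tensor.bin_width)


def individual_divergence_point(prop_target: np.ndarray,
                                prop_agent: np.ndarray,
                                bin_starts: np.ndarray,
                                window: tuple[float, float] = DP_SEARCH_WINDOW_MS,
                                run_bins: int = DEFAULT_RUN_BINS
                                ) -> float | None:
    """Onset of the first sustained run of target > agent-related looking.

    Sustained means at least ``run_bins`` consecutive bins with a strictly
    greater across-trial target proportion.  Returns the start time (ms) of
    the run, or None if no qualifying run exists in the window.
    """
    in_win = (bin_starts >= window[0]) & (bin_starts < window[1])
    idx = np.nonzero(in_win)[0]
    above = prop_target[idx] > prop_agent[idx]
    count = 0
    for k, flag in enumerate(above):
        count = count + 1 if flag else 0
        if count >= run_bins:
            return float(bin_starts[idx[k - run_bins + 1]])
    return None


def participant_indices(tensor: BinnedFixationTensor,
                        series: LogRatioSeries | None = None,
                        window: tuple[float, float] = PREDICTION_WINDOW_MS,
                        dp_window: tuple[float, float] = DP_SEARCH_WINDOW_MS,
                        run_bins: int = DEFAULT_RUN_BINS) -> pd.DataFrame:
    """Per-participant prediction-efficiency indices.

    ``log_ratio_index``: mean log-gaze proportion ratio over bins fully
    inside the prediction window (0-1300 ms -> bins 0..25).
    ``individual_dp_ms``: onset of sustained target-over-agent-related
    looking (run criterion; NaN when never observed — downstream analyses
    drop such participants pairwise).
    """
    series = series or log_ratio_series(tensor, level="trial")
    starts = tensor.bin_starts()
    full_bins = np.nonzero((starts >= window[0])
                           & (starts + tensor.bin_width <= window[1] + 1e-9))[0]
    sf = series.frame
    idx_vals = (sf[sf["bin"].isin(full_bins)]
                .groupby("participant_id", sort=False)["log_ratio"].mean())

    props = tensor.participant_proportions()
    it = tensor.condition_index("target")
    ia = tensor.condition_index("agent_related")
    rows = []
    for k, pid in enumerate(tensor.participants):
        dp = individual_divergence_point(
            props[k, :, it], props[k, :, ia], starts, dp_window, run_bins)
        rows.append({
            "participant_id": pid, "group": tensor.groups[k],
            "log_ratio_index": float(idx_vals[pid]),
            "individual_dp_ms": np.nan if dp is None else dp,
            "dp_run_bins": run_bins,
        })
    return pd.DataFrame(rows)
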