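"""Correlations between prediction-efficiency indices and autism measures,
and the behavioral-accuracy group comparison.

Pearson correlations (two-sided p, Fisher-z 95% CI) are computed for:
CARS x {log-ratio index, divergence point} in the autistic group; AQ total
x both indices per group; and the five AQ subscales x both indices per
group, Benjamini-Hochberg adjusted within each family of five subscales
(one family per group x index).  Missing individual divergence points are
dropped pairwise; CARS correlations exist only where CARS exists.

Behavioral accuracy is compared with a logistic mixed model
correct ~ group + (1 | participant) + (1 | trial), fitted by the Laplace
approximation (see :mod:`vwpgaze.glmm`); complete separation is detected,
flagged, and handled with a ridge-penalized fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.stats.multitest import multipletests

from .glmm import fit_logistic_mixed
from .io import AQ_SUBSCALES

INDEX_COLUMNS = ("log_ratio_index", "individual_dp_ms")
MIN_N = 3


def fisher_ci(r: float, n: int, ci: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n <= 3 or abs(r) >= 1:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + ci / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def _pearson(x: pd.Series, y: pd.Series) -> dict:
    mask = x.notna() & y.notna()
    n = int(mask.sum())
    if n < MIN_N:
        return {"n": n, "r": np.nan, "p": np.nan, "ci_lo": np.nan,
                "ci_hi": np.nan, "reason": f"n={n} < {MIN_N}"}
    xv, yv = x[mask].to_numpy(float), y[mask].to_numpy(float)
    if np.std(xv) == 0 or np.std(yv) == 0:
        return {"n": n, "r": np.nan, "p": np.nan, "ci_lo": np.nan,
                "ci_hi": np.nan, "reason": "zero variance"}
    r, p = stats.pearsonr(xv, yv)
    lo, hi = fisher_ci(r, n)
    return {"n": n, "r": float(r), "p": float(p), "ci_lo": lo, "ci_hi": hi,
            "reason": ""}


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, idempotent)."""
    pvals = np.asarray(pvals, float)
    ok = ~np.isnan(pvals)
    out = np.full(pvals.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    return out


def correlation_suite(indices: pd.DataFrame,
                      scores: pd.DataFrame) -> pd.DataFrame:
    """All index-by-measure Pearson correlations with FDR families.

    ``indices``: output of :func:`vwpgaze.timecourse.participant_indices`.
    ``scores``: validated score table.  Rows carry the FDR family label for
    subscale tests ("<group>:<index>:aq_subscales"); total-score and CARS
    tests are unadjusted (fdr_p = NaN).
    """
    merged = indices.merge(scores, on="participant_id", how="inner",
                           suffixes=("", "_score"))
    rows = []

    def add(scope_df, scope, index, measure, family=""):
        res = _pearson(scope_df[measure], scope_df[index])
        rows.append({"scope": scope, "index": index, "measure": measure,
                     "family": family, "fdr_p": np.nan, **res})

    aut = merged[merged["group"] == "autistic"]
    for index in INDEX_COLUMNS:
        add(aut, "autistic", index, "cars_total")
    for group, sub in merged.groupby("group"):
        for index in INDEX_COLUMNS:
            add(sub, group, index, "aq_total")
            family = f"{group}:{index}:aq_subscales"
            for measure in AQ_SUBSCALES:
                add(sub, group, index, measure, family)

    out = pd.DataFrame(rows)
    for family, fam_idx in out.groupby("family").groups.items():
        if family:
            out.loc[fam_idx, "fdr_p"] = bh_adjust(
                out.loc[fam_idx, "p"].to_numpy())
    return out.loc[:, ["scope", "index", "measure", "n", "r", "p", "ci_lo",
                       "ci_hi", "family", "fdr_p", "reason"]]


@dataclass
class AccuracyFit:
    """Group effect on per-trial correctness from the logistic mixed model."""

    coef: float                  # group coefficient B (log-odds)
    se: float
    z: float
    p: float
    reference: str
    vc_sd: dict[str, float] = field(default_factory=dict)
    separated: bool = False
    table: pd.DataFrame | None = None


def accuracy_model(responses: pd.DataFrame, reference: str = "NT",
                   include_trial_intercept: bool = True) -> AccuracyFit:
    """Fit correct ~ group + (1|participant) [+ (1|trial)].

    ``responses`` needs columns participant_id, trial_id, group, correct.
    Complete separation (a group whose outcomes are all identical) is
    flagged and triggers a ridge-penalized fallback (Gaussian penalty,
    SD 5 on the log-odds scale) so the estimate stays finite — never a
    silent divergence.
    """
    df = responses.copy()
    groups = sorted(df["group"].unique())
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} absent")
    df["group_c"] = (df["group"] != reference).astype(float)
    separated = bool(
        (df.groupby("group")["correct"].nunique() < 2).any())

    factors = {"participant": df["participant_id"].to_numpy()}
    if include_trial_intercept and df["trial_id"].nunique() > 1:
        factors["trial"] = df["trial_id"].to_numpy()
    X = np.column_stack([np.ones(len(df)), df["group_c"].to_numpy(float)])
    res = fit_logistic_mixed(
        df["correct"].to_numpy(float), X, factors,
        exog_names=["(Intercept)", "group"],
        ridge=1.0 / 25.0 if separated else 0.0)
    coef = float(res.params[1])
    se = float(res.bse[1])
    z = coef / se
    p = float(2 * stats.norm.sf(abs(z)))
    table = pd.DataFrame({
        "term": res.exog_names,
        "estimate": res.params, "se": res.bse,
    })
    return AccuracyFit(coef, se, z, p, reference, dict(res.vc_sd), separated,
                       table)
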