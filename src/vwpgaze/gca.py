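"""Growth-curve analysis of the log-ratio time course.

The model is a linear mixed-effects regression of the log-gaze proportion
ratio on orthogonal polynomial time terms (orders 1..k over the 50 bin
centres), their interactions with group, optional participant-level
covariates, and crossed random intercepts for participants and trials:

    y ~ 1 + ot1 + ... + otk + group + ot1:group + ... + otk:group
        (+ covariates) + (1 | participant) + (1 | trial)

The NT group is the reference level.  Final estimates use REML; the
likelihood-ratio order selection compares maximum-likelihood fits.  Wald
p-values use a residual-degrees-of-freedom approximation (n_obs minus the
number of fixed effects), recorded in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .timecourse import LogRatioSeries

ORTHO_TOL = 1e-10
DEFAULT_K = 4
REFERENCE_GROUP = "NT"


def orthogonal_time_basis(n_bins: int, k: int) -> np.ndarray:
    """Orthonormal polynomial basis of orders 1..k over n_bins time points.

    Columns have zero mean and unit norm, are mutually orthogonal (and
    orthogonal to the intercept), and are signed to correlate positively
    with the corresponding centred raw power.  Equivalent to Gram-Schmidt
    on the raw powers, computed via QR for numerical stability.
    """
    if k >= n_bins:
        raise ValueError(f"polynomial order k={k} must be < n_bins={n_bins}")
    if k < 1:
        raise ValueError("k must be >= 1")
    t = np.arange(n_bins, dtype=float)
    tc = (t - t.mean()) / (t.std() if n_bins > 1 else 1.0)
    raw = np.vander(tc, k + 1, increasing=True)
    q, r = np.linalg.qr(raw)
    basis = q[:, 1:k + 1]
    # QR sign is arbitrary; fix it against the centred raw powers
    signs = np.sign(np.diag(r)[1:k + 1])
    signs[signs == 0] = 1.0
    return basis * signs


@dataclass
class GrowthFit:
    """Fixed effects, variance components and metadata of a GCA fit."""

    table: pd.DataFrame              # term, estimate, se, t, p
    vc: dict[str, float]             # participant_var, trial_var, resid_var
    k: int
    reference: str
    loglik: float
    n_obs: int
    df_resid: int
    df_method: str = "between-within"
    reml: bool = True
    converged: bool = True
    dropped_components: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "se"])

    def p(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])


def _design_frame(series: LogRatioSeries, k: int,
                  covariates: pd.DataFrame | None,
                  reference: str) -> tuple[pd.DataFrame, list[str]]:
    df = series.frame.copy()
    n_bins = int(df["bin"].max()) + 1
    basis = orthogonal_time_basis(n_bins, k)
    terms = []
    for j in range(k):
        name = f"ot{j + 1}"
        df[name] = basis[df["bin"], j]
        terms.append(name)
    groups = sorted(set(df["group"]))
    if len(groups) == 2:
        other = next(g for g in groups if g != reference)
        if reference not in groups:
            raise ValueError(f"reference group {reference!r} absent")
        df["group_c"] = (df["group"] == other).astype(float)
    elif len(groups) == 1:
        df["group_c"] = 0.0
    else:
        raise ValueError("expected one or two groups")
    cov_names: list[str] = []
    if covariates is not None:
        cov = covariates.set_index("participant_id")
        cov_names = [c for c in cov.columns]
        for c in cov_names:
            vals = df["participant_id"].map(cov[c])
            df[c] = (vals - vals.mean()) / vals.std()
    if "trial_id" not in df.columns:
        df["trial_id"] = 0
    return df, terms + cov_names


def _fit_mixedlm(df: pd.DataFrame, terms: list[str], two_groups: bool,
                 reml: bool, drop: set[str]
                 ) -> tuple[sm.regression.mixed_linear_model.MixedLMResults, list[str]]:
    poly = [t for t in terms if t.startswith("ot")]
    fixed = list(poly)
    if two_groups:
        fixed += ["group_c"] + [f"{t}:group_c" for t in poly]
        for t in poly:
            df[f"{t}:group_c"] = df[t] * df["group_c"]
    fixed += [t for t in terms if not t.startswith("ot")]
    exog = sm.add_constant(df[fixed], has_constant="add")
    vc_formula = {}
    if "participant" not in drop:
        vc_formula["participant"] = "0 + C(participant_id)"
    if "trial" not in drop and df["trial_id"].nunique() > 1:
        vc_formula["trial"] = "0 + C(trial_id)"
    ones = np.ones(len(df))
    if vc_formula:
        model = sm.MixedLM.from_formula(
            "log_ratio ~ " + " + ".join(["1"] + fixed),
            data=df, groups=ones, vc_formula=vc_formula, re_formula="0")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            res = model.fit(reml=reml, method="lbfgs", maxiter=200)
            if not res.converged:
                # lbfgs can stall when a variance sits on the zero boundary;
                # powell is slower but robust there
                res = model.fit(reml=reml, method="powell", maxiter=500)
        return res, list(exog.columns)
    res = sm.OLS(df["log_ratio"], exog).fit()
    return res, list(exog.columns)


def fit_growth_model(series: LogRatioSeries, k: int = DEFAULT_K,
                     covariates: pd.DataFrame | None = None,
                     reference: str = REFERENCE_GROUP,
                     reml: bool = True) -> GrowthFit:
    """Fit the growth model at polynomial order ``k``.

    ``covariates`` (optional): participant-level frame with a
    ``participant_id`` column; each remaining column enters standardized as
    a fixed effect.  A singular random-effect structure (a variance
    component estimated at zero with failed convergence) triggers one
    refit without the offending component, flagged in the result.
    """
    df, terms = _design_frame(series, k, covariates, reference)
    two_groups = df["group_c"].nunique() > 1
    dropped: list[str] = []
    res, names = _fit_mixedlm(df, terms, two_groups, reml, set(dropped))
    if getattr(res, "converged", True) is False and hasattr(res, "vcomp"):
        vcs = dict(zip(res.model.exog_vc.names, np.atleast_1d(res.vcomp)))
        dropped = [name for name, var in vcs.items() if var < 1e-8]
        if dropped:
            res, names = _fit_mixedlm(df, terms, two_groups, reml,
                                      set(dropped))

    params = np.asarray(res.params)[:len(names)]
    bse = np.asarray(res.bse)[:len(names)]
    n_obs = len(df)
    df_resid = n_obs - len(names)
    # between-within df: terms constant within participant (intercept,
    # group, covariates) are tested against participant-level df, terms
    # varying over time against residual df
    n_participants = df["participant_id"].nunique()
    between = [n for n in names
               if not n.startswith("ot")]
    df_between = max(n_participants - len(between), 1)
    term_df = np.array([df_between if n in between else df_resid
                        for n in names])
    tvals = params / bse
    pvals = 2 * stats.t.sf(np.abs(tvals), term_df)
    pretty = {"const": "(Intercept)", "group_c": "group"}
    names_out = [pretty.get(n, n.replace(":group_c", ":group")) for n in names]
    table = pd.DataFrame({
        "term": names_out,
        "estimate": params, "se": bse, "t": tvals, "p": pvals,
        "df": term_df,
    })
    vc = {"resid_var": float(res.scale)}
    if hasattr(res, "vcomp") and res.vcomp is not None and len(res.vcomp):
        for name, var in zip(res.model.exog_vc.names, res.vcomp):
            vc[f"{name}_var"] = float(var)
    llf = float(res.llf)
    converged = bool(getattr(res, "converged", True))
    return GrowthFit(table, vc, k, reference, llf, n_obs, df_resid,
                     reml=reml, converged=converged,
                     dropped_components=dropped)


def select_order(series: LogRatioSeries, k_max: int = 5,
                 alpha: float = 0.05,
                 covariates: pd.DataFrame | None = None,
                 reference: str = REFERENCE_GROUP
                 ) -> tuple[int, pd.DataFrame]:
    """Forward likelihood-ratio selection of the polynomial order.

    ML fits at k = 1..k_max are compared sequentially; adding order k
    contributes the time term plus its group interaction (2 df with two
    groups, 1 df otherwise).  Selection stops at the first non-significant
    addition and returns the last significant order.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    fits = {}
    rows = []
    selected = 1
    prev = None
    two_groups = series.frame["group"].nunique() > 1
    for k in range(1, k_max + 1):
        fit = fit_growth_model(series, k=k, covariates=covariates,
                               reference=reference, reml=False)
        fits[k] = fit
        if prev is None:
            rows.append({"k": k, "loglik": fit.loglik, "lr_stat": np.nan,
                         "df": np.nan, "p": np.nan, "selected": True})
            prev = fit
            continue
        lr = 2 * (fit.loglik - prev.loglik)
        ddf = 2 if two_groups else 1
        p = float(stats.chi2.sf(max(lr, 0.0), ddf))
        significant = p < alpha
        rows.append({"k": k, "loglik": fit.loglik, "lr_stat": lr,
                     "df": ddf, "p": p, "selected": significant})
        if not significant:
            break
        selected = k
        prev = fit
    return selected, pd.DataFrame(rows)


def simulate_growth_data(n_per_group: int = 8, n_trials: int = 12,
                         n_bins: int = 50, k: int = 4,
                         coeffs: dict[str, float] | None = None,
                         sd_participant: float = 0.2, sd_trial: float = 0.1,
                         sd_resid: float = 0.5,
                         seed: int | None = None) -> LogRatioSeries:
    """Generate a log-ratio series directly from the growth model.

    ``coeffs`` maps term names ("(Intercept)", "ot1".."otk", "group",
    "ot1:group"...) to true values; omitted terms are zero.  Used for
    parameter-recovery and type-I-error studies where the true polynomial
    coefficients must be known exactly.
    """
    rng = np.random.default_rng(seed)
    coeffs = coeffs or {}
    basis = orthogonal_time_basis(n_bins, k)
    n_p = 2 * n_per_group
    group_c = np.repeat([0.0, 1.0], n_per_group)      # 0 = NT reference
    u_p = rng.normal(0, sd_participant, n_p)
    u_t = rng.normal(0, sd_trial, n_trials)

    pid = np.repeat(np.arange(n_p), n_trials * n_bins)
    tid = np.tile(np.repeat(np.arange(n_trials), n_bins), n_p)
    b = np.tile(np.arange(n_bins), n_p * n_trials)
    g = group_c[pid]
    y = np.full(len(b), coeffs.get("(Intercept)", 0.0))
    y += coeffs.get("group", 0.0) * g
    for j in range(k):
        y += coeffs.get(f"ot{j + 1}", 0.0) * basis[b, j]
        y += coeffs.get(f"ot{j + 1}:group", 0.0) * basis[b, j] * g
    y += u_p[pid] + u_t[tid] + rng.normal(0, sd_resid, len(b))

    groups = np.where(g == 0, "NT", "autistic")
    frame = pd.DataFrame({
        "participant_id": [f"p{i:03d}" for i in pid], "group": groups,
        "trial_id": tid, "bin": b,
        "t_ms": b * 50.0, "log_ratio": y,
    })
    return LogRatioSeries(frame, "trial")
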