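"""Logistic mixed model with crossed random intercepts, via the Laplace
approximation.

Fits  logit P(y=1) = X b + sum_f u_f[g_f],  u_f ~ N(0, sigma_f^2 I)
for one or more crossed grouping factors (here: participants and trials).
The marginal likelihood is approximated by Laplace's method around the
joint (b, u) mode — the same approximation lme4's ``glmer`` uses with
nAGQ=1 — with the variance parameters optimized on the log-sd scale by
scipy.  Wald standard errors for the fixed effects come from the fixed-
effect block of the inverse joint Hessian at the mode.

This is a minimal engine for the behavioral-accuracy comparison, not a
general GLMM package: binomial family with logit link only, random
intercepts only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse


@dataclass
class LogisticMixedResult:
    params: np.ndarray               # fixed effects b
    bse: np.ndarray                  # Wald SEs
    vc_sd: dict[str, float]          # random-intercept SDs
    loglik: float                    # Laplace marginal log-likelihood
    exog_names: list[str]
    converged: bool
    penalized: bool = False          # ridge applied (separation fallback)
    n_obs: int = 0
    ranef: dict[str, np.ndarray] = field(default_factory=dict)


def _build_z(groups: dict[str, np.ndarray]) -> tuple[np.ndarray, list[tuple[str, int]]]:
    cols = []
    blocks = []
    for name, codes in groups.items():
        codes = np.asarray(codes)
        levels = np.unique(codes)
        idx = np.searchsorted(levels, codes)
        z = np.zeros((len(codes), len(levels)))
        z[np.arange(len(codes)), idx] = 1.0
        cols.append(z)
        blocks.append((name, len(levels)))
    return np.hstack(cols), blocks


def _joint_mode(y, X, Z, d_inv, beta0, u0, ridge=0.0, maxiter=50, tol=1e-10):
    """Penalized IRLS for the joint (beta, u) mode at fixed variances."""
    n, p = X.shape
    q = Z.shape[1]
    C = np.hstack([X, Z])
    theta = np.concatenate([beta0, u0])
    pen = np.concatenate([np.full(p, ridge), d_inv])
    ll_old = -np.inf
    for _ in range(maxiter):
        eta = C @ theta
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(y @ eta - np.logaddexp(0, eta).sum()
                   - 0.5 * np.sum(pen * theta ** 2))
        w = mu * (1 - mu)
        grad = C.T @ (y - mu) - pen * theta
        H = (C.T * w) @ C
        H[np.diag_indices_from(H)] += pen + 1e-12
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # dampen if the penalized likelihood would decrease
        lam = 1.0
        for _ in range(30):
            cand = theta + lam * step
            eta_c = C @ cand
            ll_c = float(y @ eta_c - np.logaddexp(0, eta_c).sum()
                         - 0.5 * np.sum(pen * cand ** 2))
            if ll_c >= ll - 1e-12:
                break
            lam /= 2
        theta = theta + lam * step
        if abs(ll_c - ll_old) < tol * (abs(ll_old) + 1):
            break
        ll_old = ll_c
    return theta[:p], theta[p:], H


def _laplace_loglik(log_sd, y, X, Z, blocks, ridge, state):
    p = X.shape[1]
    d_inv = np.concatenate([
        np.full(nlev, np.exp(-2 * ls))
        for (name, nlev), ls in zip(blocks, log_sd)])
    beta, u, H = _joint_mode(y, X, Z, d_inv, state["beta"], state["u"], ridge)
    state["beta"], state["u"] = beta, u
    eta = X @ beta + Z @ u
    ll_cond = float(y @ eta - np.logaddexp(0, eta).sum())
    ll_pen = -0.5 * float(np.sum(d_inv * u ** 2))
    # log det of the u-block of the Hessian and of the prior covariance
    H_uu = H[p:, p:]
    sign, logdet = np.linalg.slogdet(H_uu)
    log_det_d = float(np.sum([2 * ls * nlev
                              for (name, nlev), ls in zip(blocks, log_sd)]))
    ll = ll_cond + ll_pen - 0.5 * log_det_d - 0.5 * logdet
    state["H"] = H
    return -ll


def fit_logistic_mixed(y, X, groups: dict[str, np.ndarray],
                       exog_names: list[str] | None = None,
                       ridge: float = 0.0) -> LogisticMixedResult:
    """Fit the Laplace-approximate logistic mixed model.

    ``groups`` maps factor name -> per-observation level codes.  ``ridge``
    adds a Gaussian penalty on the fixed effects (used as the separation
    fallback).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Z, blocks = _build_z(groups)
    p = X.shape[1]
    state = {"beta": np.zeros(p), "u": np.zeros(Z.shape[1])}
    x0 = np.full(len(blocks), np.log(0.5))
    res = optimize.minimize(
        _laplace_loglik, x0, args=(y, X, Z, blocks, ridge, state),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 200 * len(blocks)})
    # evaluate once more at the optimum to refresh the cached mode/Hessian
    neg_ll = _laplace_loglik(res.x, y, X, Z, blocks, ridge, state)
    H = state["H"]
    cov_beta = np.linalg.inv(H)[:p, :p]
    bse = np.sqrt(np.maximum(np.diag(cov_beta), 0))
    vc_sd = {name: float(np.exp(ls))
             for (name, _), ls in zip(blocks, res.x)}
    offsets = np.cumsum([0] + [nlev for _, nlev in blocks])
    ranef = {name: state["u"][offsets[i]:offsets[i + 1]]
             for i, (name, _) in enumerate(blocks)}
    return LogisticMixedResult(
        params=state["beta"], bse=bse, vc_sd=vc_sd, loglik=-neg_ll,
        exog_names=exog_names or [f"x{i}" for i in range(p)],
        converged=bool(res.success), penalized=ridge > 0,
        n_obs=len(y), ranef=ranef)
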