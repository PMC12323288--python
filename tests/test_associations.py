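"""Index-score correlations, FDR over AQ subscales, accuracy GLMM."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from vwpgaze.associations import (accuracy_model, bh_adjust,
                                  correlation_suite, fisher_ci)
from vwpgaze.io import AQ_SUBSCALES, SCORE_COLUMNS
from vwpgaze.synthetic import CohortSpec, simulate_cohort_tensor
from vwpgaze.timecourse import participant_indices


def make_scores(n, group="autistic", rng=None):
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame({"participant_id": [f"{group[:2]}{k}" for k in range(n)],
                       "group": group,
                       "age": 5.0, "verbal_iq": 100.0,
                       "cars_total": rng.normal(35, 3, n)
                       if group == "autistic" else np.nan,
                       "aq_total": 0.0})
    for sub in AQ_SUBSCALES:
        df[sub] = rng.normal(15, 3, n)
    df["aq_total"] = df[list(AQ_SUBSCALES)].sum(axis=1)
    return df[list(SCORE_COLUMNS)]


def make_indices(scores, log_ratio_index, dp=None):
    return pd.DataFrame({
        "participant_id": scores["participant_id"],
        "group": scores["group"],
        "log_ratio_index": log_ratio_index,
        "individual_dp_ms": np.nan if dp is None else dp,
        "dp_run_bins": 4,
    })


def test_hand_computed_pearson():
    from vwpgaze.associations import _pearson
    res = _pearson(pd.Series([1., 2, 3, 4, 5]), pd.Series([2., 1, 4, 3, 5]))
    assert res["r"] == pytest.approx(0.8, abs=1e-12)
    assert res["ci_lo"] < 0.8 < res["ci_hi"]


def test_perfect_linearity():
    from vwpgaze.associations import _pearson
    x = pd.Series(np.arange(10.0))
    res = _pearson(x, 2 * x + 1)
    assert res["r"] == pytest.approx(1.0)
    assert res["p"] < 1e-10


def test_fisher_ci_contains_r():
    lo, hi = fisher_ci(0.5, 30)
    assert lo < 0.5 < hi
    assert fisher_ci(0.5, 3) == (pytest.approx(np.nan, nan_ok=True),) * 2


def test_bh_equal_pvalues_are_fixed_point():
    p = np.full(5, 0.03)
    assert np.allclose(bh_adjust(p), 0.03)


@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=10))
@settings(max_examples=80, deadline=None)
def test_bh_monotone_and_bounded(pvals):
    """Adjusted p-values never fall below the raw ones, never exceed the
    Bonferroni bound (capped at 1), and preserve the raw ordering."""
    p = np.array(pvals)
    m = len(p)
    adj = bh_adjust(p)
    assert (adj >= p - 1e-12).all()
    assert (adj <= np.minimum(m * p, 1.0) + 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_correlation_suite_structure_and_families():
    rng = np.random.default_rng(5)
    scores = pd.concat([make_scores(20, "autistic", rng),
                        make_scores(20, "NT", rng)], ignore_index=True)
    indices = make_indices(scores, rng.normal(size=40),
                           rng.uniform(800, 2000, 40))
    out = correlation_suite(indices, scores)
    # CARS rows only for the autistic scope
    cars = out[out.measure == "cars_total"]
    assert set(cars.scope) == {"autistic"}
    # one FDR family of five subscales per (group, index)
    fams = out[out.family != ""].groupby("family").size()
    assert (fams == 5).all()
    assert len(fams) == 4
    sub = out[out.family != ""]
    assert (sub["fdr_p"] >= sub["p"] - 1e-12).all()
    # AQ-total and CARS rows are unadjusted
    assert out[out.family == ""]["fdr_p"].isna().all()


def test_missing_dps_removed_pairwise():
    rng = np.random.default_rng(6)
    scores = make_scores(12, "autistic", rng)
    dp = rng.uniform(800, 2000, 12)
    dp[:4] = np.nan
    indices = make_indices(scores, rng.normal(size=12), dp)
    out = correlation_suite(indices, scores)
    n_dp = out[(out["index"] == "individual_dp_ms")
               & (out.measure == "cars_total")]["n"].iloc[0]
    n_lr = out[(out["index"] == "log_ratio_index")
               & (out.measure == "cars_total")]["n"].iloc[0]
    assert n_dp == 8 and n_lr == 12


def test_undefined_correlation_below_min_n():
    scores = make_scores(5, "autistic")
    dp = np.full(5, np.nan)
    dp[:2] = [900.0, 1000.0]
    indices = make_indices(scores, np.arange(5.0), dp)
    out = correlation_suite(indices, scores)
    row = out[(out["index"] == "individual_dp_ms")
              & (out.measure == "cars_total")].iloc[0]
    assert np.isnan(row["r"])
    assert "n=2" in row["reason"]


def test_suite_recovers_injected_link_sign():
    """With the default score link, AQ total correlates negatively with the
    log-ratio index in nearly every simulated cohort."""
    neg = 0
    n_rep = 30
    for i in range(n_rep):
        tc = simulate_cohort_tensor(CohortSpec(seed=300 + i))
        out = correlation_suite(participant_indices(tc.tensor), tc.scores)
        rows = out[(out.measure == "aq_total")
                   & (out["index"] == "log_ratio_index")]
        neg += (rows["r"] < 0).all()
    assert neg >= 0.9 * n_rep


# ---------------------------------------------------------------------------
# Accuracy GLMM


def sim_responses(n_aut, n_nt, n_trials, b_group, sd_participant, seed,
                  base=1.5, sd_trial=0.3):
    rng = np.random.default_rng(seed)
    u_t = rng.normal(0, sd_trial, n_trials)
    rows = []
    for group, n in (("NT", n_nt), ("autistic", n_aut)):
        for k in range(n):
            lo = base + (b_group if group == "autistic" else 0.0) \
                + rng.normal(0, sd_participant)
            correct = rng.random(n_trials) < expit(lo + u_t)
            for t, c in enumerate(correct):
                rows.append({"participant_id": f"{group}{k}", "group": group,
                             "trial_id": t, "correct": int(c)})
    return pd.DataFrame(rows)


def test_accuracy_null_effect_within_2se():
    ok = 0
    n_rep = 25
    for i in range(n_rep):
        fit = accuracy_model(sim_responses(20, 20, 24, 0.0, 0.8, seed=i))
        ok += abs(fit.coef) < 2 * fit.se
    assert ok >= 0.85 * n_rep


def test_accuracy_recovers_logit_difference():
    ok = 0
    n_rep = 20
    for i in range(n_rep):
        fit = accuracy_model(
            sim_responses(45, 52, 24, 1.0, 0.8, seed=100 + i))
        ok += abs(fit.coef - 1.0) < 2 * fit.se
    assert ok >= 0.85 * n_rep


def test_all_correct_flags_separation():
    df = sim_responses(6, 6, 12, 0.0, 0.0, seed=1)
    df["correct"] = 1
    fit = accuracy_model(df)
    assert fit.separated
    assert np.isfinite(fit.coef)


def test_reference_group_must_exist():
    df = sim_responses(4, 4, 6, 0.0, 0.0, seed=2)
    with pytest.raises(ValueError, match="reference"):
        accuracy_model(df, reference="controls")


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_glmm_matches_lme4_oracle(tmp_path):
    """Independent cross-check of the Laplace GLMM against lme4::glmer."""
    df = sim_responses(20, 20, 24, 0.8, 0.8, seed=42)
    fit = accuracy_model(df)
    path = tmp_path / "resp.csv"
    df.to_csv(path, index=False)
    script = f"""
    suppressMessages(library(lme4))
    df <- read.csv("{path}")
    df$group_c <- as.numeric(df$group != "NT")
    m <- glmer(correct ~ group_c + (1|participant_id) + (1|trial_id),
               data=df, family=binomial)
    s <- summary(m)$coefficients
    vc <- sqrt(unlist(VarCorr(m)))
    cat(s["group_c","Estimate"], s["group_c","Std. Error"],
        vc[["participant_id"]], vc[["trial_id"]], sep="\\n")
    """
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    coef_r, se_r, sd_p_r, sd_t_r = map(float, out.stdout.split())
    assert fit.coef == pytest.approx(coef_r, abs=0.08)
    assert fit.se == pytest.approx(se_r, abs=0.03)
    assert fit.vc_sd["participant"] == pytest.approx(sd_p_r, abs=0.05)
    assert fit.vc_sd["trial"] == pytest.approx(sd_t_r, abs=0.05)
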