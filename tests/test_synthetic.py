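"""Synthetic gaze generator: latent process, cohort tables, reproducibility."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from vwpgaze.io import CONDITIONS, AQ_SUBSCALES
from vwpgaze.preprocessing import detect_fixations_trial, default_layout
from vwpgaze.synthetic import (CohortSpec, GroupParams, NoiseParams,
                               ScoreLink, build_stimulus_set, default_lexicon,
                               latent_probabilities, simulate_cohort,
                               simulate_cohort_tensor, simulate_trial_gaze,
                               _sample_states, _segment_bounds)

DESIGN = build_stimulus_set(default_lexicon())[0]
NO_NOISE = NoiseParams(spatial_jitter_sd_px=0.0, sample_noise_sd_px=0.0,
                       blink_rate_hz=0.0)


def pure_ramp_params(latency=150.0, slope=40.0):
    """Target probability equals the verb ramp exactly; all else zero."""
    return GroupParams(
        onset_latency_ms=latency, target_bias=1.0, latency_sd_ms=0.0,
        bias_sd=0.0, ramp_slope_ms=slope, start_prob=0.0,
        agent_ramp_midpoint_ms=-1e4, action_bump=0.0, agent_floor=0.0,
        baseline_probs={"target": 0.0, "agent_related": 0.0,
                        "action_related": 0.0, "unrelated": 0.0})


def test_trial_has_300_samples_at_120hz():
    gp = CohortSpec().group_params["NT"]
    df, occ = simulate_trial_gaze(DESIGN, 775.0, 0.5, gp, NoiseParams(),
                                  np.random.default_rng(0))
    assert len(df) == 300
    assert occ.shape == (50, len(CONDITIONS))
    assert np.allclose(np.diff(df["t_ms"]), 1000 / 120)


def test_degenerate_single_aoi_yields_one_fixation():
    gp = dataclasses.replace(
        pure_ramp_params(), onset_latency_ms=0.0,
        start_prob=0.0,
        baseline_probs={"target": 1.0, "agent_related": 0.0,
                        "action_related": 0.0, "unrelated": 0.0})
    gp.validate()
    df, occ = simulate_trial_gaze(DESIGN, 0.0, 1.0, gp, NO_NOISE,
                                  np.random.default_rng(1))
    assert occ[:, 0].all()
    fixations = detect_fixations_trial(df, CohortSpec().geometry)
    assert len(fixations) == 1
    layout = default_layout()
    pos = layout.position_at(fixations[0].x, fixations[0].y)
    assert DESIGN.condition_of_position[pos] == "target"


def test_latent_probabilities_form_a_simplex():
    for group, gp in CohortSpec().group_params.items():
        t = np.linspace(0, 2500, 501)
        probs = latent_probabilities(t, gp.onset_latency_ms, gp.max_bias, gp)
        assert probs.min() >= -1e-12
        assert probs.sum(axis=1).max() <= 1 + 1e-12


def test_occupancy_ramp_crossing_near_900ms():
    """With a 150-ms latency the target occupancy curve crosses 50% at
    verb_onset + 150 = 900 ms (Monte-Carlo at the latent level)."""
    gp = pure_ramp_params()
    bounds = _segment_bounds(150.0)
    mids = (bounds[:-1] + bounds[1:]) / 2
    probs = latent_probabilities(mids, 150.0, 1.0, gp)
    rng = np.random.default_rng(0)
    states = _sample_states(rng, np.broadcast_to(probs, (10000,) + probs.shape))
    starts = np.arange(50) * 50.0
    seg_of_bin = np.searchsorted(bounds, starts, side="right") - 1
    occ = (states[:, seg_of_bin] == 0).mean(axis=0)
    centers = starts + 25
    k = int(np.argmax(occ >= 0.5))
    cross = centers[k - 1] + (0.5 - occ[k - 1]) * 50 / (occ[k] - occ[k - 1])
    assert abs(cross - 900.0) <= 25.0


def test_occupancy_matches_generating_ramp_within_3_se():
    gp = CohortSpec().group_params["NT"]
    spec = CohortSpec(n_per_group={"autistic": 2, "NT": 2},
                      group_params={"autistic": gp, "NT": gp}, seed=5)
    spec = dataclasses.replace(spec, group_params={
        "autistic": dataclasses.replace(gp, latency_sd_ms=0.0, bias_sd=0.0),
        "NT": dataclasses.replace(gp, latency_sd_ms=0.0, bias_sd=0.0)})
    n_rep = 4000
    bounds = _segment_bounds(150.0)
    mids = (bounds[:-1] + bounds[1:]) / 2
    probs = latent_probabilities(mids, gp.onset_latency_ms, gp.target_bias, gp)
    rng = np.random.default_rng(2)
    states = _sample_states(rng, np.broadcast_to(probs, (n_rep,) + probs.shape))
    for cond in range(4):
        emp = (states == cond).mean(axis=0)
        se = np.sqrt(probs[:, cond] * (1 - probs[:, cond]) / n_rep)
        assert (np.abs(emp - probs[:, cond]) <= 3 * se + 1e-12).all()


def test_blink_gaps_cover_both_interpolation_branches():
    gp = CohortSpec().group_params["NT"]
    noise = NoiseParams(blink_rate_hz=2.0)
    rng = np.random.default_rng(3)
    short = long = 0
    for _ in range(50):
        df, _ = simulate_trial_gaze(DESIGN, 775.0, 0.5, gp, noise, rng)
        invalid = (df["l_valid"] == 0).to_numpy()
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, invalid, 0])))[::2]
        short += int((runs * (1000 / 120) <= 75).sum())
        long += int((runs * (1000 / 120) > 75).sum())
    assert short > 0 and long > 0


def test_cohort_shapes_and_scores():
    spec = CohortSpec(n_per_group={"autistic": 3, "NT": 4}, seed=2)
    data = simulate_cohort(spec)
    assert len(data.gaze) == 7
    assert len(data.scores) == 7
    assert data.designs["trial_id"].nunique() == 24
    assert all(len(t.samples) == 24 * 300 for t in data.gaze.values())
    # CARS only for the autistic group, AQ total = subscale sum
    sc = data.scores
    assert sc.loc[sc.group == "NT", "cars_total"].isna().all()
    assert sc.loc[sc.group == "autistic", "cars_total"].notna().all()
    assert np.allclose(sc["aq_total"], sc[list(AQ_SUBSCALES)].sum(axis=1))
    # ground truth recorded per participant
    assert len(data.ground_truth.participants) == 7
    assert set(data.ground_truth.participants.columns) >= {
        "participant_id", "group", "latency_ms", "bias"}


def test_cohort_too_small_rejected():
    with pytest.raises(ValueError, match="n_per_group"):
        CohortSpec(n_per_group={"autistic": 1, "NT": 5}).validate()


def test_reproducibility_is_byte_identical(tmp_path):
    from vwpgaze.synthetic import write_cohort
    spec = CohortSpec(n_per_group={"autistic": 2, "NT": 2}, seed=9)
    for sub in ("a", "b"):
        write_cohort(simulate_cohort(spec), tmp_path / sub)
    for name in ("scores.csv", "designs.csv", "responses.csv",
                 "ground_truth.csv", "latent_tensor.csv"):
        assert (tmp_path / "a" / name).read_bytes() == \
            (tmp_path / "b" / name).read_bytes()
    for f in sorted((tmp_path / "a" / "gaze").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / "gaze" / f.name).read_bytes()


def test_zero_score_link_decouples_scores_from_latents():
    """With all link coefficients zeroed the within-group AQ-latency
    correlation is null (mean over seeds ~ 0)."""
    rs = []
    for seed in range(10):
        tc = simulate_cohort_tensor(
            CohortSpec(score_link=ScoreLink.zeroed(), seed=seed))
        merged = tc.scores.merge(
            tc.ground_truth.participants[
                ["participant_id", "latency_ms", "bias"]],
            on="participant_id")
        for _, sub in merged.groupby("group"):
            rs.append(np.corrcoef(sub["aq_total"], sub["latency_ms"])[0, 1])
    assert abs(np.mean(rs)) < 0.1


def test_score_link_injects_negative_aq_bias_coupling():
    """The default link couples higher AQ to slower/weaker prediction, so
    AQ total correlates negatively with realized target bias."""
    tc = simulate_cohort_tensor(CohortSpec(seed=21))
    merged = tc.scores.merge(
        tc.ground_truth.participants[["participant_id", "latency_ms", "bias"]],
        on="participant_id")
    for group, sub in merged.groupby("group"):
        assert np.corrcoef(sub["aq_total"], sub["bias"])[0, 1] < 0
        assert np.corrcoef(sub["aq_total"], sub["latency_ms"])[0, 1] > 0


def test_invalid_group_params_rejected():
    with pytest.raises(ValueError):
        GroupParams(onset_latency_ms=775.0, target_bias=1.5).validate()
    with pytest.raises(ValueError):
        GroupParams(onset_latency_ms=-5.0, target_bias=0.5).validate()
    with pytest.raises(ValueError):
        # exceeds the post-verb probability budget
        GroupParams(onset_latency_ms=775.0, target_bias=0.95).validate()
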