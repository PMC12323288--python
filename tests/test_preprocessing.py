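"""I-VT fixation filter, AOI assignment and binning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import SAMPLE_DT, make_trial_frame, tensor_from_array
from vwpgaze.io import CONDITIONS, ScreenGeometry
from vwpgaze.preprocessing import (AOILayout, AOILayoutError, Fixation,
                                   FixationParams, assign_aoi, bin_fixations,
                                   default_layout, detect_fixations_trial,
                                   merge_fixations)

GEO = ScreenGeometry()
LAYOUT = default_layout(GEO)
COND_OF_POS = {0: "target", 1: "agent_related", 2: "action_related",
               3: "unrelated"}


def times(n):
    return np.arange(n) * SAMPLE_DT


def test_constant_gaze_yields_single_full_trial_fixation():
    t = times(300)
    frame = make_trial_frame(t, np.full(300, 480.0), np.full(300, 270.0))
    fixations = detect_fixations_trial(frame, GEO)
    assert len(fixations) == 1
    fix = fixations[0]
    assert fix.onset_ms == 0.0
    assert fix.offset_ms == pytest.approx(2500.0)
    assert (fix.x, fix.y) == (480.0, 270.0)
    assert fix.source == "binocular"


def test_short_stable_segment_is_dropped():
    # 90 ms of valid data (11 samples) in an otherwise invalid trial
    t = times(120)
    valid = np.zeros(120, int)
    valid[50:61] = 1
    frame = make_trial_frame(t, np.full(120, 480.0), np.full(120, 270.0),
                             valid)
    assert detect_fixations_trial(frame, GEO) == []


def test_gap_at_most_75ms_interpolated_into_one_fixation():
    # stable gaze with a 60-ms invalid gap: interpolation bridges it
    t = times(300)
    valid = np.ones(300, int)
    valid[100:107] = 0           # 7 samples ~ 58 ms
    frame = make_trial_frame(t, np.full(300, 480.0), np.full(300, 270.0),
                             valid)
    fixations = detect_fixations_trial(frame, GEO)
    assert len(fixations) == 1
    assert fixations[0].duration_ms == pytest.approx(2500.0)


def test_gap_over_75ms_not_interpolated_two_fixations():
    # a 100-ms invalid gap (12 samples) splits the trial; no merge because
    # the fixation interval exceeds 75 ms
    t = times(300)
    valid = np.ones(300, int)
    valid[144:156] = 0
    frame = make_trial_frame(t, np.full(300, 480.0), np.full(300, 270.0),
                             valid)
    fixations = detect_fixations_trial(frame, GEO)
    assert len(fixations) == 2
    gap = fixations[1].onset_ms - fixations[0].offset_ms
    assert gap > 75.0


def test_monocular_fallback_is_labelled():
    t = times(300)
    frame = make_trial_frame(t, np.full(300, 480.0), np.full(300, 270.0))
    frame[["rx", "ry"]] = np.nan
    frame["r_valid"] = 0
    fixations = detect_fixations_trial(frame, GEO)
    assert len(fixations) == 1
    assert fixations[0].source == "left_only"


def test_saccade_between_aois_separates_fixations():
    t = times(300)
    x = np.where(t < 1200, 480.0, 1440.0)
    y = np.full(300, 270.0)
    frame = make_trial_frame(t, x, y)
    fixations = detect_fixations_trial(frame, GEO)
    assert len(fixations) == 2
    assert fixations[0].x == pytest.approx(480.0)
    assert fixations[1].x == pytest.approx(1440.0)


def test_merge_rule_is_conjunctive():
    params = FixationParams()
    close = [Fixation(0, 200, 100.0, 100.0), Fixation(260, 400, 105.0, 100.0)]
    merged = merge_fixations(list(close), params, GEO)
    assert len(merged) == 1
    assert merged[0].onset_ms == 0 and merged[0].offset_ms == 400

    far_in_time = [Fixation(0, 200, 100.0, 100.0),
                   Fixation(290, 430, 105.0, 100.0)]
    assert len(merge_fixations(far_in_time, params, GEO)) == 2

    far_in_space = [Fixation(0, 200, 100.0, 100.0),
                    Fixation(260, 400, 150.0, 100.0)]  # ~1.2 degrees away
    assert len(merge_fixations(far_in_space, params, GEO)) == 2


@given(st.lists(
    st.tuples(st.integers(0, 40), st.integers(3, 12),
              st.floats(0, 1900), st.floats(0, 1070)),
    min_size=0, max_size=8))
@settings(max_examples=60, deadline=None)
def test_merging_is_idempotent(raw):
    params = FixationParams()
    fixations = [Fixation(50.0 * s, 50.0 * (s + d), x, y)
                 for s, d, x, y in raw]
    once = merge_fixations(fixations, params, GEO)
    twice = merge_fixations(list(once), params, GEO)
    assert once == twice


def test_lower_min_duration_never_loses_fixations():
    rng = np.random.default_rng(0)
    t = times(300)
    # piecewise-constant gaze switching AOIs every ~20 samples
    anchors = rng.choice([480.0, 1440.0], size=15)
    x = np.repeat(anchors, 20) + rng.normal(0, 1.5, 300)
    y = np.full(300, 270.0) + rng.normal(0, 1.5, 300)
    frame = make_trial_frame(t, x, y)
    strict = detect_fixations_trial(frame, GEO, FixationParams())
    loose = detect_fixations_trial(
        frame, GEO, FixationParams(min_duration_ms=40.0))
    assert len(loose) >= len(strict)


def test_missing_geometry_is_an_error():
    frame = make_trial_frame(times(10), np.ones(10), np.ones(10))
    with pytest.raises(ValueError, match="geometry"):
        detect_fixations_trial(frame, None)


# ---------------------------------------------------------------------------
# AOI layout and assignment


def test_default_layout_geometry():
    for pos in range(4):
        cx, cy = LAYOUT.center(pos)
        assert 0 <= cx < GEO.width_px and 0 <= cy < GEO.height_px
    d0 = np.hypot(LAYOUT.center(0)[0] - GEO.width_px / 2,
                  LAYOUT.center(0)[1] - GEO.height_px / 2)
    for pos in range(1, 4):
        d = np.hypot(LAYOUT.center(pos)[0] - GEO.width_px / 2,
                     LAYOUT.center(pos)[1] - GEO.height_px / 2)
        assert d == pytest.approx(d0)


def test_overlapping_layout_rejected():
    with pytest.raises(AOILayoutError):
        AOILayout({0: (0.0, 0.0), 1: (100.0, 100.0)}, size_px=384)


@pytest.mark.parametrize("point, expected", [
    ((480.0, 270.0), "target"),              # AOI centre
    ((960.0, 540.0), None),                  # screen centre, between AOIs
    ((288.0, 78.0), "target"),               # top-left corner inclusive
    ((672.0, 270.0), None),                  # right edge exclusive
    ((480.0, 462.0), None),                  # bottom edge exclusive
])
def test_assign_aoi_half_open_boundaries(point, expected):
    fix = Fixation(0, 200, point[0], point[1])
    assert assign_aoi(fix, LAYOUT, COND_OF_POS) == expected


# ---------------------------------------------------------------------------
# Binning


def test_fixation_120_to_480_covers_bins_2_through_9():
    fix = Fixation(120.0, 480.0, 480.0, 270.0)
    occ = bin_fixations([fix], LAYOUT, COND_OF_POS)
    target = occ[:, CONDITIONS.index("target")]
    assert target[2:10].all()
    assert target[:2].sum() == 0 and target[10:].sum() == 0
    assert occ[:, 1:].sum() == 0


def test_no_fixations_all_zero_and_bin_count():
    occ = bin_fixations([], LAYOUT, COND_OF_POS)
    assert occ.shape == (50, 4)
    assert occ.sum() == 0


def test_bin_width_must_divide_window():
    with pytest.raises(ValueError, match="divide"):
        bin_fixations([], LAYOUT, COND_OF_POS, window=(0, 2500), bin_width=33)


def test_binning_is_monotone_in_fixations():
    rng = np.random.default_rng(1)
    fixations = [Fixation(float(s), float(s + d),
                          *LAYOUT.center(rng.integers(4)))
                 for s, d in rng.integers([0, 100], [2300, 500], (10, 2))]
    base = bin_fixations(fixations[:-1], LAYOUT, COND_OF_POS)
    more = bin_fixations(fixations, LAYOUT, COND_OF_POS)
    assert (more >= base).all()


def test_zero_noise_recovery_matches_latent():
    """End-to-end: noise-free synthetic gaze preprocessed back into exactly
    the generator's latent occupancy tensor."""
    from vwpgaze.preprocessing import preprocess_cohort
    from vwpgaze.synthetic import CohortSpec, NoiseParams, simulate_cohort
    spec = CohortSpec(
        n_per_group={"autistic": 2, "NT": 2},
        noise=NoiseParams(spatial_jitter_sd_px=0.0, sample_noise_sd_px=0.0,
                          blink_rate_hz=0.0),
        seed=3)
    data = simulate_cohort(spec)
    tensor = preprocess_cohort(list(data.gaze.values()), data.designs)
    assert np.array_equal(tensor.data, data.latent.data)
    assert tensor.participants == data.latent.participants


def test_noisy_recovery_close_to_latent(small_cohort):
    from vwpgaze.preprocessing import preprocess_cohort
    data = small_cohort
    tensor = preprocess_cohort(list(data.gaze.values()), data.designs)
    agreement = (tensor.data == data.latent.data).mean()
    assert agreement > 0.97


def test_total_fixation_time_bounded_per_trial(small_cohort):
    from vwpgaze.preprocessing import detect_fixations
    data = small_cohort
    table = next(iter(data.gaze.values()))
    fixations = detect_fixations(table)
    by_trial = {}
    for f in fixations:
        by_trial.setdefault(f.trial_id, 0.0)
        by_trial[f.trial_id] += f.duration_ms
    assert all(v <= 2500.0 + 1e-6 for v in by_trial.values())
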