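"""Counterbalanced stimulus designs and two-group synthetic gaze cohorts.

The generator stands in for recorded gaze data so that every downstream
stage (fixation filtering, binning, CPA, GCA, DPA, correlations) is testable
against known ground truth.

Stimulus side: sentence quadruplets are built by cross-pairing two agents
with two actions; each of the four resulting sentences assigns the four
patient images to the four conditions (target / agent-related /
action-related / unrelated) so that within a quadruplet every image serves
every condition exactly once, and every condition occupies every screen
position exactly once.

Gaze side: each trial's latent gaze state follows a time-inhomogeneous
categorical process over the four AOIs plus an explicit off-AOI background
state.  Before verb onset the process is biased toward the target and
agent-related AOIs; after verb onset the target probability follows a
logistic ramp whose midpoint sits ``onset_latency_ms`` after the verb, the
agent-related probability declines complementarily, and the action-related
AOI receives a transient Gaussian bump.  The state is redrawn on a fixed
150-ms grid (so dwells survive the 100-ms minimum-duration filter), gaze
points are the AOI centre plus spatial jitter, both eyes are sampled at
120 Hz with per-sample noise, and blinks appear as validity-flagged gaps of
50-300 ms (exercising both the interpolation and the non-interpolation
branches of the 75-ms gap rule).

Participant scores (CARS, AQ total and five subscales) are generated from
each participant's realized latency and target bias through configurable
linear links with Gaussian noise, so that score-index correlations have a
known injected sign and magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import (AQ_SUBSCALES, CONDITIONS, DESIGN_COLUMNS, GROUPS,
                 GazeTable, ScreenGeometry, SCORE_COLUMNS)
from .preprocessing import (BinnedFixationTensor, DEFAULT_BIN_WIDTH,
                            DEFAULT_WINDOW, default_layout)

# Sentence timing landmarks (ms from sentence onset).
AGENT_ONSET_MS = 0.0
VERB_ONSET_MS = 750.0
PATIENT_ONSET_MS = 1300.0
SENTENCE_OFFSET_MS = 2100.0
WINDOW_END_MS = 2500.0

LANDMARKS = {
    "agent_onset": AGENT_ONSET_MS,
    "verb_onset": VERB_ONSET_MS,
    "patient_onset": PATIENT_ONSET_MS,
    "sentence_offset": SENTENCE_OFFSET_MS,
    "window_end": WINDOW_END_MS,
}

#: Latent state is redrawn on this grid; a multiple of the 50-ms bin width
#: and >= 150 ms so noise-free dwells survive the minimum-duration filter.
STATE_DWELL_MS = 150.0


class InvalidLexiconError(ValueError):
    pass


class RandomizationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Quadruplet:
    """Two agents x two actions and the four patients they select.

    ``patients[i][j]`` is the patient of sentence (agents[i], actions[j]).
    """

    agents: tuple[str, str]
    actions: tuple[str, str]
    patients: tuple[tuple[str, str], tuple[str, str]]

    def validate(self) -> None:
        flat = [p for row in self.patients for p in row]
        for name, words in [("agents", self.agents), ("actions", self.actions),
                            ("patients", flat)]:
            if len(set(words)) != len(words):
                raise InvalidLexiconError(
                    f"duplicate {name} in quadruplet {words}")


@dataclass(frozen=True)
class Lexicon:
    quadruplets: tuple[Quadruplet, ...]

    def validate(self) -> None:
        for q in self.quadruplets:
            q.validate()


def default_lexicon() -> Lexicon:
    """Six quadruplets of child-familiar agents, actions and patients."""
    raw = [
        (("bird", "worker"), ("eats", "builds"),
         (("worm", "nest"), ("rice", "building"))),
        (("cat", "girl"), ("catches", "draws"),
         (("mouse", "butterfly"), ("fish", "flower"))),
        (("frog", "boy"), ("jumps_on", "reads"),
         (("lilypad", "storybook"), ("bed", "sign"))),
        (("dog", "baby"), ("chews", "hugs"),
         (("bone", "ball"), ("biscuit", "teddy"))),
        (("monkey", "grandma"), ("peels", "knits"),
         (("banana", "orange"), ("scarf", "sweater"))),
        (("horse", "chef"), ("pulls", "bakes"),
         (("cart", "sled"), ("bread", "cake"))),
    ]
    return Lexicon(tuple(Quadruplet(a, v, p) for a, v, p in raw))


@dataclass
class TrialDesign:
    """One sentence trial: condition/word layout plus timing landmarks."""

    trial_id: int
    quadruplet_id: int
    sentence_id: int                         # 1..4 within the quadruplet
    condition_of_position: dict[int, str]    # screen position -> condition
    word_of_position: dict[int, str]
    landmarks: dict[str, float] = field(default_factory=lambda: dict(LANDMARKS))
    agent: str = ""
    action: str = ""

    @property
    def target_position(self) -> int:
        return next(p for p, c in self.condition_of_position.items()
                    if c == "target")

    def validate(self) -> None:
        conds = sorted(self.condition_of_position.values())
        if conds != sorted(CONDITIONS):
            raise ValueError(f"trial {self.trial_id}: each condition must "
                             "appear exactly once across positions")
        marks = [self.landmarks[k] for k in
                 ("agent_onset", "verb_onset", "patient_onset",
                  "sentence_offset", "window_end")]
        if not all(a < b for a, b in zip(marks, marks[1:])):
            raise ValueError(f"trial {self.trial_id}: landmarks not "
                             "strictly increasing")


def build_stimulus_set(lexicon: Lexicon) -> list[TrialDesign]:
    """Expand a lexicon into its fully balanced trial designs.

    Four sentences per quadruplet; within a quadruplet the word-by-condition
    incidence matrix is a 4x4 permutation-balanced Latin square, and a
    cyclic Latin square places each condition once at each screen position.
    """
    lexicon.validate()
    designs: list[TrialDesign] = []
    trial_id = 0
    for qid, quad in enumerate(lexicon.quadruplets):
        for s in range(4):
            i, j = divmod(s, 2)
            word_of_condition = {
                "target": quad.patients[i][j],
                "agent_related": quad.patients[i][1 - j],
                "action_related": quad.patients[1 - i][j],
                "unrelated": quad.patients[1 - i][1 - j],
            }
            cond_of_pos = {(s + k) % 4: cond
                           for k, cond in enumerate(CONDITIONS)}
            design = TrialDesign(
                trial_id=trial_id, quadruplet_id=qid, sentence_id=s + 1,
                condition_of_position=cond_of_pos,
                word_of_position={p: word_of_condition[c]
                                  for p, c in cond_of_pos.items()},
                agent=quad.agents[i], action=quad.actions[j])
            design.validate()
            designs.append(design)
            trial_id += 1
    return designs


def check_randomization(designs: Sequence[TrialDesign]) -> bool:
    """True iff an ordering satisfies both pseudo-randomization constraints:

    no target position repeated on more than two consecutive trials, and no
    two adjacent trials from the same quadruplet.
    """
    positions = [d.target_position for d in designs]
    for k in range(len(designs) - 2):
        if positions[k] == positions[k + 1] == positions[k + 2]:
            return False
    return all(a.quadruplet_id != b.quadruplet_id
               for a, b in zip(designs, designs[1:]))


def pseudo_randomize(designs: Sequence[TrialDesign], seed: int,
                     max_restarts: int = 1000) -> list[TrialDesign]:
    """Seeded constrained shuffle; raises if no valid order is found."""
    designs = list(designs)
    if not designs:
        return []
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        order = rng.permutation(len(designs))
        candidate = [designs[i] for i in order]
        if check_randomization(candidate):
            return candidate
    raise RandomizationError(
        f"no constraint-satisfying order found in {max_restarts} restarts")


def designs_to_frame(designs: Sequence[TrialDesign]) -> pd.DataFrame:
    rows = []
    for d in designs:
        for pos in sorted(d.condition_of_position):
            rows.append({
                "trial_id": d.trial_id, "quadruplet_id": d.quadruplet_id,
                "sentence_id": d.sentence_id, "position": pos,
                "condition": d.condition_of_position[pos],
                "word": d.word_of_position[pos],
            })
    return pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))


# ---------------------------------------------------------------------------
# Cohort specification


@dataclass(frozen=True)
class GroupParams:
    """Latent fixation-process parameters of one participant group.

    The process has three phases.  All four AOIs start at ``start_prob``;
    an agent-onset ramp (logistic, midpoint ``agent_ramp_midpoint_ms``)
    raises target and agent-related occupancy to their ``baseline_probs``
    levels; after verb onset a second logistic ramp — midpoint
    ``onset_latency_ms`` after the verb — carries the target to
    ``target_bias`` while the agent-related AOI falls back to
    ``agent_floor``, and the action-related AOI receives a transient
    Gaussian bump.  The unrelated AOI stays at its baseline throughout.
    """

    onset_latency_ms: float           # verb-ramp midpoint delay after verb
    target_bias: float                # asymptotic target probability
    latency_sd_ms: float = 80.0       # between-participant latency SD
    bias_sd: float = 0.035
    ramp_slope_ms: float = 80.0       # verb-ramp logistic scale
    start_prob: float = 0.12          # common pre-agent occupancy, all AOIs
    agent_ramp_midpoint_ms: float = 800.0
    agent_ramp_slope_ms: float = 140.0
    action_bump: float = 0.06         # peak extra action-related probability
    bump_center_ms: float = 1700.0    # absolute time of the bump peak
    bump_width_ms: float = 350.0
    agent_floor: float = 0.10         # post-ramp agent-related probability
    baseline_probs: Mapping[str, float] = field(default_factory=lambda: {
        "target": 0.22, "agent_related": 0.22,
        "action_related": 0.12, "unrelated": 0.12})
    accuracy: float = 0.95

    @property
    def max_bias(self) -> float:
        """Largest target bias keeping every per-time probability row <= 1."""
        b = self.baseline_probs
        return 1.0 - (self.agent_floor + b["action_related"]
                      + self.action_bump + b["unrelated"])

    def validate(self) -> None:
        probs = dict(self.baseline_probs)
        if sorted(probs) != sorted(CONDITIONS):
            raise ValueError("baseline_probs must cover the four conditions")
        vals = list(probs.values()) + [self.target_bias, self.agent_floor,
                                       self.action_bump, self.accuracy,
                                       self.start_prob]
        if any(not 0 <= v <= 1 for v in vals):
            raise ValueError("probabilities must lie in [0, 1]")
        if sum(probs.values()) > 1 + 1e-9:
            raise ValueError("baseline AOI probabilities exceed 1")
        if self.target_bias > self.max_bias + 1e-9:
            raise ValueError(
                f"target_bias {self.target_bias} exceeds the probability "
                f"budget ({self.max_bias:.3f}); reduce it or the other "
                "post-verb probabilities")
        if self.agent_floor > self.start_prob + probs["agent_related"]:
            raise ValueError("agent_floor above reachable range")
        if self.onset_latency_ms < 0 or self.ramp_slope_ms <= 0 \
                or self.agent_ramp_slope_ms <= 0:
            raise ValueError("latencies must be >= 0 and slopes > 0")
        # dense check that AOI probabilities + background stay a simplex
        t = np.linspace(0.0, WINDOW_END_MS, 251)
        probs_t = latent_probabilities(t, self.onset_latency_ms,
                                       min(self.target_bias, self.max_bias),
                                       self)
        if probs_t.min() < -1e-9 or probs_t.sum(axis=1).max() > 1 + 1e-9:
            raise ValueError("latent probabilities leave [0, 1] simplex")


@dataclass(frozen=True)
class NoiseParams:
    spatial_jitter_sd_px: float = 35.0   # per-dwell offset from AOI centre
    sample_noise_sd_px: float = 2.0      # per-sample, per-eye tremor
    blink_rate_hz: float = 0.15
    blink_min_ms: float = 50.0           # uniform blink-duration range brackets
    blink_max_ms: float = 300.0          # the 75-ms interpolation limit

    def validate(self) -> None:
        if self.blink_min_ms > self.blink_max_ms:
            raise ValueError("blink_min_ms > blink_max_ms")
        if min(self.spatial_jitter_sd_px, self.sample_noise_sd_px,
               self.blink_rate_hz, self.blink_min_ms) < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class MeasureLink:
    """Linear link from latent (latency, bias) z-scores to one score."""

    base: Mapping[str, float]            # group -> mean
    noise_sd: Mapping[str, float]        # group -> residual SD
    coef_latency: float = 0.0            # score units per SD of latency
    coef_bias: float = 0.0               # score units per SD of target bias


def _default_measures() -> dict[str, MeasureLink]:
    return {
        "cars_total": MeasureLink({"autistic": 35.6}, {"autistic": 2.4},
                                  coef_latency=0.9, coef_bias=-0.9),
        "aq_social_skills": MeasureLink(
            {"autistic": 18.0, "NT": 10.0}, {"autistic": 3.5, "NT": 2.2},
            coef_latency=1.2, coef_bias=-1.2),
        "aq_attention_switching": MeasureLink(
            {"autistic": 19.0, "NT": 10.0}, {"autistic": 3.5, "NT": 2.0},
            coef_latency=1.3, coef_bias=-1.3),
        "aq_attention_to_detail": MeasureLink(
            {"autistic": 17.0, "NT": 10.0}, {"autistic": 4.0, "NT": 2.5},
            coef_latency=0.3, coef_bias=-0.3),
        "aq_communication": MeasureLink(
            {"autistic": 19.0, "NT": 10.0}, {"autistic": 3.0, "NT": 2.0},
            coef_latency=1.6, coef_bias=-1.6),
        "aq_imagination": MeasureLink(
            {"autistic": 16.0, "NT": 9.0}, {"autistic": 3.5, "NT": 2.0},
            coef_latency=0.5, coef_bias=-0.5),
    }


@dataclass(frozen=True)
class ScoreLink:
    """Links from latent parameters to every simulated score.

    AQ total is the sum of the five subscales, mirroring how the instrument
    is scored; CARS is generated for the autistic group only.
    """

    measures: Mapping[str, MeasureLink] = field(
        default_factory=_default_measures)
    accuracy_coef_latency: float = -0.3   # logit units per SD
    accuracy_coef_bias: float = 0.4

    @classmethod
    def zeroed(cls) -> "ScoreLink":
        measures = {k: replace(v, coef_latency=0.0, coef_bias=0.0)
                    for k, v in _default_measures().items()}
        return cls(measures, 0.0, 0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to simulate a two-group cohort reproducibly."""

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"autistic": 45, "NT": 52})
    group_params: Mapping[str, GroupParams] = field(
        default_factory=lambda: {
            # NT: earlier verb-ramp midpoint and stronger asymptotic target
            # bias; the autistic group lags by 127 ms with a weaker bias.
            "NT": GroupParams(onset_latency_ms=775.0, target_bias=0.54,
                              accuracy=0.959),
            "autistic": GroupParams(onset_latency_ms=866.0, target_bias=0.46,
                                    accuracy=0.934),
        })
    noise: NoiseParams = field(default_factory=NoiseParams)
    score_link: ScoreLink = field(default_factory=ScoreLink)
    n_trials: int = 24
    seed: int = 0
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    state_dwell_ms: float = STATE_DWELL_MS

    def validate(self) -> None:
        if set(self.n_per_group) - set(GROUPS):
            raise ValueError(f"groups must be among {GROUPS}")
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(
                    f"n_per_group[{g!r}] = {n} < 2: statistics undefined")
            if g not in self.group_params:
                raise ValueError(f"missing group_params for {g!r}")
        for gp in self.group_params.values():
            gp.validate()
        self.noise.validate()
        if self.state_dwell_ms % DEFAULT_BIN_WIDTH:
            raise ValueError("state_dwell_ms must be a multiple of the "
                             "50-ms bin width")


@dataclass
class GroundTruth:
    """Realized per-participant latent parameters and the group-level shift."""

    participants: pd.DataFrame        # participant_id, group, latency, bias
    group_divergence_shift_ms: float  # true between-group ramp-midpoint lag

    def latency(self, participant_id) -> float:
        df = self.participants
        return float(df.loc[df["participant_id"] == participant_id,
                            "latency_ms"].iloc[0])


# ---------------------------------------------------------------------------
# Latent process


def latent_probabilities(t_ms: np.ndarray, latency_ms: float, bias: float,
                         gp: GroupParams) -> np.ndarray:
    """AOI occupancy probabilities at times ``t_ms``; shape (len(t), 4).

    Residual probability (1 - row sum) is the off-AOI background state.
    """
    t = np.asarray(t_ms, dtype=float)
    b = gp.baseline_probs
    b0 = gp.start_prob
    # a participant's latency deviation shifts both ramps (a shared timing
    # trait) and their bias scales both plateau elevations, so individual
    # differences are visible before the verb ramp completes
    dev = latency_ms - gp.onset_latency_ms
    scale = bias / gp.target_bias if gp.target_bias > 0 else 1.0
    sa = expit((t - (gp.agent_ramp_midpoint_ms + dev))
               / gp.agent_ramp_slope_ms)
    sv = expit((t - (VERB_ONSET_MS + latency_ms)) / gp.ramp_slope_ms)
    bump = gp.action_bump * np.exp(
        -0.5 * ((t - gp.bump_center_ms) / gp.bump_width_ms) ** 2)
    elev_t = (b["target"] - b0) * scale
    elev_a = (b["agent_related"] - b0) * scale
    probs = np.empty((len(t), len(CONDITIONS)))
    probs[:, 0] = b0 + elev_t * sa + (bias - (b0 + elev_t)) * sv
    probs[:, 1] = b0 + elev_a * sa - (b0 + elev_a - gp.agent_floor) * sv
    probs[:, 2] = b["action_related"] + bump
    probs[:, 3] = b["unrelated"]
    return probs


def _segment_bounds(dwell_ms: float, end_ms: float = WINDOW_END_MS,
                    phase_ms: float = 0.0) -> np.ndarray:
    """Dwell-segment boundaries covering [0, end).

    ``phase_ms`` shifts the grid (in bin-width steps, drawn per trial) so
    that boundaries are not shared across trials and participants — shared
    boundaries would quantize group-average curves to the dwell grid.  The
    first segment absorbs the phase and a short final remainder is absorbed
    into the last full segment, so every segment is at least ``dwell_ms``
    long and all boundaries stay bin-aligned.
    """
    bounds = np.arange(phase_ms + dwell_ms, end_ms, dwell_ms)
    bounds = np.concatenate([[0.0], bounds])
    if end_ms - bounds[-1] < dwell_ms:
        bounds = bounds[:-1]
    return np.append(bounds, end_ms)


def _sample_states(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Categorical draw per row over 4 AOI states + background (coded 4)."""
    full = np.concatenate(
        [probs, 1 - probs.sum(axis=-1, keepdims=True)], axis=-1)
    cum = np.cumsum(full, axis=-1)
    u = rng.random(probs.shape[:-1] + (1,))
    return (u >= cum[..., :-1]).sum(axis=-1)


def simulate_trial_gaze(design: TrialDesign, latency_ms: float, bias: float,
                        gp: GroupParams, noise: NoiseParams,
                        rng: np.random.Generator,
                        geometry: ScreenGeometry | None = None,
                        state_dwell_ms: float = STATE_DWELL_MS,
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate one trial's 120-Hz binocular samples.

    Returns the sample frame (columns lx..r_valid, t_ms on the exact 120-Hz
    grid) and the latent (n_bins, 4) AOI bin occupancy implied by the drawn
    dwell states.
    """
    geometry = geometry or ScreenGeometry()
    layout = default_layout(geometry)
    pos_of_cond = {c: p for p, c in design.condition_of_position.items()}

    n_phases = max(1, int(state_dwell_ms // DEFAULT_BIN_WIDTH))
    phase = float(rng.integers(n_phases)) * DEFAULT_BIN_WIDTH
    bounds = _segment_bounds(state_dwell_ms, phase_ms=phase)
    mids = (bounds[:-1] + bounds[1:]) / 2
    probs = latent_probabilities(mids, latency_ms, bias, gp)
    states = _sample_states(rng, probs)

    # anchor point per dwell segment: AOI centre (or a background point near
    # the screen centre) plus a per-dwell jitter
    anchors = np.empty((len(states), 2))
    for k, s in enumerate(states):
        if s < len(CONDITIONS):
            anchors[k] = layout.center(pos_of_cond[CONDITIONS[s]])
        else:
            anchors[k] = (geometry.width_px / 2, geometry.height_px / 2)
    anchors += rng.normal(0, noise.spatial_jitter_sd_px, anchors.shape)
    anchors[:, 0] = np.clip(anchors[:, 0], 1, geometry.width_px - 2)
    anchors[:, 1] = np.clip(anchors[:, 1], 1, geometry.height_px - 2)

    n_samples = int(round(WINDOW_END_MS / 1000.0 * geometry.sampling_rate_hz))
    t = np.arange(n_samples) * (1000.0 / geometry.sampling_rate_hz)
    seg = np.searchsorted(bounds, t, side="right") - 1
    base = anchors[seg]

    eyes = {}
    for eye in "lr":
        pts = base + rng.normal(0, noise.sample_noise_sd_px, base.shape)
        eyes[eye] = pts
    valid = np.ones(n_samples, dtype=bool)

    if noise.blink_rate_hz > 0:
        n_blinks = rng.poisson(noise.blink_rate_hz * WINDOW_END_MS / 1000.0)
        starts = rng.uniform(0, WINDOW_END_MS, n_blinks)
        durs = rng.uniform(noise.blink_min_ms, noise.blink_max_ms, n_blinks)
        for s0, d in zip(starts, durs):
            valid &= ~((t >= s0) & (t < s0 + d))

    df = pd.DataFrame({
        "t_ms": t,
        "lx": eyes["l"][:, 0], "ly": eyes["l"][:, 1],
        "rx": eyes["r"][:, 0], "ry": eyes["r"][:, 1],
        "l_valid": valid.astype(np.int8), "r_valid": valid.astype(np.int8),
    })
    df.loc[~valid, ["lx", "ly", "rx", "ry"]] = np.nan

    n_bins = int(round(WINDOW_END_MS / DEFAULT_BIN_WIDTH))
    occupancy = np.zeros((n_bins, len(CONDITIONS)), dtype=np.uint8)
    bin_starts = np.arange(n_bins) * DEFAULT_BIN_WIDTH
    seg_of_bin = np.searchsorted(bounds, bin_starts, side="right") - 1
    for b, k in enumerate(seg_of_bin):
        if states[k] < len(CONDITIONS):
            occupancy[b, states[k]] = 1
    return df, occupancy


# ---------------------------------------------------------------------------
# Cohort simulation


def _draw_participants(spec: CohortSpec,
                       rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group in sorted(spec.n_per_group):  # deterministic group order
        gp = spec.group_params[group]
        n = spec.n_per_group[group]
        lat = rng.normal(gp.onset_latency_ms, gp.latency_sd_ms, n)
        lat = np.clip(lat, 0.0, 1500.0)
        # keep bias within the validated probability budget
        bias = np.clip(rng.normal(gp.target_bias, gp.bias_sd, n),
                       gp.baseline_probs["target"] + 0.02, gp.max_bias)
        for k in range(n):
            rows.append({"participant_id": f"{group[:2]}{k + 1:03d}",
                         "group": group, "latency_ms": lat[k],
                         "bias": bias[k]})
    return pd.DataFrame(rows)


def _latent_z(participants: pd.DataFrame, spec: CohortSpec
              ) -> tuple[np.ndarray, np.ndarray]:
    """Group-centred z-scores of realized latency and bias."""
    z_lat = np.empty(len(participants))
    z_bias = np.empty(len(participants))
    for group, gp in spec.group_params.items():
        m = (participants["group"] == group).to_numpy()
        z_lat[m] = (participants.loc[m, "latency_ms"]
                    - gp.onset_latency_ms) / gp.latency_sd_ms
        z_bias[m] = (participants.loc[m, "bias"] - gp.target_bias) / gp.bias_sd
    return z_lat, z_bias


def _simulate_scores(spec: CohortSpec, participants: pd.DataFrame,
                     rng: np.random.Generator) -> pd.DataFrame:
    z_lat, z_bias = _latent_z(participants, spec)
    n = len(participants)
    groups = participants["group"].to_numpy()
    out = pd.DataFrame({"participant_id": participants["participant_id"],
                        "group": groups})
    age_rng = {"autistic": (3.8, 8.05), "NT": (3.02, 7.04)}
    viq = {"autistic": (105.91, 17.15), "NT": (109.69, 10.93)}
    out["age"] = [rng.uniform(*age_rng[g]) for g in groups]
    out["verbal_iq"] = [max(71.0, rng.normal(*viq[g])) for g in groups]

    link = spec.score_link
    for name, ml in link.measures.items():
        vals = np.full(n, np.nan)
        for group in spec.n_per_group:
            if group not in ml.base:
                continue
            m = groups == group
            vals[m] = (ml.base[group]
                       + ml.coef_latency * z_lat[m]
                       + ml.coef_bias * z_bias[m]
                       + rng.normal(0, ml.noise_sd[group], int(m.sum())))
        out[name] = vals
    out["aq_total"] = out[list(AQ_SUBSCALES)].sum(axis=1, min_count=5)
    return out.loc[:, list(SCORE_COLUMNS)]


def _simulate_responses(spec: CohortSpec, participants: pd.DataFrame,
                        trial_ids: Sequence[int],
                        rng: np.random.Generator) -> pd.DataFrame:
    z_lat, z_bias = _latent_z(participants, spec)
    link = spec.score_link
    rows = []
    for k, row in participants.iterrows():
        gp = spec.group_params[row["group"]]
        lo = logit(np.clip(gp.accuracy, 1e-6, 1 - 1e-6))
        # inflate the base logit so the marginal mean accuracy matches the
        # group parameter despite participant heterogeneity (logit-normal
        # mean-attenuation correction)
        sd_participant = 1.3
        lo *= np.sqrt(1 + 0.346 * sd_participant ** 2)
        p = expit(lo + link.accuracy_coef_latency * z_lat[k]
                  + link.accuracy_coef_bias * z_bias[k]
                  + rng.normal(0, sd_participant))
        correct = rng.random(len(trial_ids)) < p
        for tid, c in zip(trial_ids, correct):
            rows.append({"participant_id": row["participant_id"],
                         "group": row["group"], "trial_id": tid,
                         "correct": int(c)})
    return pd.DataFrame(rows)


@dataclass
class CohortData:
    """Everything :func:`simulate_cohort` produces."""

    gaze: dict[str, GazeTable]
    designs: pd.DataFrame                 # global long design table
    orders: pd.DataFrame                  # per-participant presentation order
    scores: pd.DataFrame
    responses: pd.DataFrame
    ground_truth: GroundTruth
    latent: BinnedFixationTensor          # generator-side bin occupancy
    spec: CohortSpec


def _true_shift(spec: CohortSpec) -> float:
    lats = [spec.group_params[g].onset_latency_ms
            for g in sorted(spec.n_per_group)]
    return float(lats[0] - lats[-1]) if len(lats) == 2 else 0.0


def simulate_cohort(spec: CohortSpec | None = None) -> CohortData:
    """Simulate gaze, design, score and response tables for a full cohort."""
    spec = spec or CohortSpec()
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    s_design, s_part, s_scores, s_resp, s_gaze = ss.spawn(5)

    designs = build_stimulus_set(default_lexicon())
    if spec.n_trials != len(designs):
        if spec.n_trials > len(designs):
            raise ValueError("n_trials exceeds the stimulus set size")
        designs = designs[:spec.n_trials]
    design_frame = designs_to_frame(designs)
    rng_design = np.random.default_rng(s_design)
    # two pseudo-randomized sequences; participants are assigned to one
    sequences = [pseudo_randomize(designs, int(rng_design.integers(2 ** 31)))
                 for _ in range(2)] if len(designs) > 2 else [designs, designs]

    rng_part = np.random.default_rng(s_part)
    participants = _draw_participants(spec, rng_part)
    seq_idx = rng_part.integers(0, len(sequences), len(participants))

    scores = _simulate_scores(spec, participants, np.random.default_rng(s_scores))
    responses = _simulate_responses(
        spec, participants, [d.trial_id for d in designs],
        np.random.default_rng(s_resp))

    trial_ids = [d.trial_id for d in designs]
    n_bins = int(round(WINDOW_END_MS / DEFAULT_BIN_WIDTH))
    latent = np.zeros((len(participants), len(trial_ids), n_bins,
                       len(CONDITIONS)))
    gaze: dict[str, GazeTable] = {}
    orders = []
    child_seeds = s_gaze.spawn(len(participants))
    for k, row in participants.iterrows():
        rng = np.random.default_rng(child_seeds[k])
        gp = spec.group_params[row["group"]]
        frames = []
        for pres, design in enumerate(sequences[seq_idx[k]]):
            df, occ = simulate_trial_gaze(
                design, row["latency_ms"], row["bias"], gp, spec.noise, rng,
                spec.geometry, spec.state_dwell_ms)
            df.insert(0, "trial_id", design.trial_id)
            frames.append(df)
            latent[k, trial_ids.index(design.trial_id)] = occ
            orders.append({"participant_id": row["participant_id"],
                           "presentation_index": pres,
                           "trial_id": design.trial_id})
        samples = pd.concat(frames, ignore_index=True)
        samples.insert(0, "participant_id", row["participant_id"])
        gaze[row["participant_id"]] = GazeTable(
            samples, row["participant_id"], spec.geometry, row["group"])

    latent_tensor = BinnedFixationTensor(
        latent, list(participants["participant_id"]), trial_ids,
        participants["group"].to_numpy(), DEFAULT_WINDOW, DEFAULT_BIN_WIDTH)
    truth = GroundTruth(participants, _true_shift(spec))
    return CohortData(gaze, design_frame, pd.DataFrame(orders), scores,
                      responses, truth, latent_tensor, spec)


@dataclass
class TensorCohort:
    tensor: BinnedFixationTensor
    scores: pd.DataFrame
    responses: pd.DataFrame
    ground_truth: GroundTruth


def simulate_cohort_tensor(spec: CohortSpec | None = None,
                           seed: int | None = None) -> TensorCohort:
    """Latent-occupancy fast path: sample the bin tensor directly.

    Draws the same latent categorical process as :func:`simulate_cohort`
    but per 50-ms bin, skipping the gaze-sample and fixation-detection
    layers.  Intended for simulation studies where thousands of cohorts are
    needed.
    """
    spec = spec or CohortSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    _, s_part, s_scores, s_resp, s_occ = ss.spawn(5)

    rng_part = np.random.default_rng(s_part)
    participants = _draw_participants(spec, rng_part)
    rng_part.integers(0, 2, len(participants))  # parity with full path

    n_bins = int(round(WINDOW_END_MS / DEFAULT_BIN_WIDTH))
    centers = (np.arange(n_bins) + 0.5) * DEFAULT_BIN_WIDTH
    rng_occ = np.random.default_rng(s_occ)
    n_p, n_t = len(participants), spec.n_trials
    data = np.zeros((n_p, n_t, n_bins, len(CONDITIONS)))
    for k, row in participants.iterrows():
        gp = spec.group_params[row["group"]]
        probs = latent_probabilities(centers, row["latency_ms"], row["bias"],
                                     gp)
        states = _sample_states(rng_occ, np.broadcast_to(
            probs, (n_t, n_bins, len(CONDITIONS))))
        onehot = states[..., None] == np.arange(len(CONDITIONS))
        data[k] = onehot

    scores = _simulate_scores(spec, participants, np.random.default_rng(s_scores))
    responses = _simulate_responses(spec, participants, list(range(n_t)),
                                    np.random.default_rng(s_resp))
    tensor = BinnedFixationTensor(
        data, list(participants["participant_id"]), list(range(n_t)),
        participants["group"].to_numpy(), DEFAULT_WINDOW, DEFAULT_BIN_WIDTH)
    return TensorCohort(tensor, scores, responses,
                        GroundTruth(participants, _true_shift(spec)))


def write_cohort(data: CohortData, out_dir) -> dict[str, object]:
    """Write a simulated cohort's tables; returns a manifest fragment."""
    from pathlib import Path

    from .io import (write_design_table, write_gaze_table, write_score_table)
    out = Path(out_dir)
    gaze_dir = out / "gaze"
    gaze_dir.mkdir(parents=True, exist_ok=True)
    for pid, table in data.gaze.items():
        write_gaze_table(table, gaze_dir / f"{pid}.tsv")
    write_design_table(data.designs, out / "designs.csv")
    data.orders.to_csv(out / "orders.csv", index=False)
    write_score_table(data.scores, out / "scores.csv")
    data.responses.to_csv(out / "responses.csv", index=False)
    data.ground_truth.participants.to_csv(
        out / "ground_truth.csv", index=False, float_format="%.17g")
    data.latent.to_csv(out / "latent_tensor.csv")
    return {"participants": len(data.gaze),
            "trials": int(data.designs["trial_id"].nunique()),
            "files": ["gaze/", "designs.csv", "orders.csv", "scores.csv",
                      "responses.csv", "ground_truth.csv",
                      "latent_tensor.csv"]}
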