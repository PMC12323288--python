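# Methods

`vwpgaze` implements the analysis chain used to measure predictive language
processing in visual-world-paradigm (VWP) eye-tracking studies that compare
an autistic and a neurotypical (NT) group of children listening to
subject-verb-object sentences while viewing four-image arrays.  This note
documents the models, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices a maintainer would want to know.

## Timeline and data representation

All times are milliseconds from sentence onset.  Landmarks: agent word at
0 ms, verb at 750 ms, patient (sentence-final object) at 1300 ms, sentence
offset at 2100 ms; the analysis window runs to 2500 ms (400 ms past
offset).  Gaze timestamps live on the exact 120-Hz grid (`i * 1000/120` as
floats) rather than rounded integer milliseconds: the minimum-duration
filter is an exact 12-sample criterion and integer rounding would make
100-ms durations fall on either side of the threshold unpredictably.

The common currency of all statistics is the **binned fixation tensor**:
binary occupancy indexed (participant, trial, 50-ms bin, condition), with
four conditions per trial — target, agent-related, action-related and
unrelated distractor — and 50 bins covering [0, 2500) ms.  Bins are
half-open `[t, t+50)`; a condition is coded 1 in a bin iff a fixation
assigned to its AOI overlaps the bin by any positive duration (a
`min_overlap_ms` option provides stricter readings).

## Stimulus construction

Sentence quadruplets cross two agents with two actions; the four resulting
patients fill the four conditions so that, within a quadruplet, every
word/image serves every condition exactly once (a 4×4 permutation-balanced
incidence), and a cyclic Latin square places every condition once at each
screen position.  Pseudo-randomized presentation orders satisfy two
constraints — the target position never repeats on more than two
consecutive trials, and adjacent trials never come from the same
quadruplet — via seeded rejection sampling with bounded restarts (an
unsatisfiable instance raises, never silently violates).

## Fixation preprocessing (I-VT)

Per trial, in order: (1) linear interpolation of invalid gaps up to 75 ms,
separately per eye; (2) binocular averaging where both eyes are valid,
single-eye fallback otherwise; (3) velocity-threshold classification at
30 deg/s (the published default for this filter class), with velocity
estimated over a 20-ms window; (4) merging of adjacent fixations separated
by at most 75 ms *and* 0.5 degrees (conjunctive), iterated to a fixed
point so merging is idempotent; (5) removal of fixations shorter than
100 ms.  Eye combination precedes classification.

Angular criteria use a flat-screen arctangent model: a 24-inch 1920×1080
display has a pixel pitch of ≈0.2766 mm, so at a 650-mm viewing distance
one degree is ≈41 px.  Both the threshold and the geometry are
configurable.

AOIs are four 384×384-px squares centred on the screen quadrants,
equidistant from the centre, with half-open containment (left/top edge in,
right/bottom edge out).  Fixations outside all AOIs are retained but
contribute to no condition, mirroring analyses that track only the four
picture regions.

## Statistical engines

**Cluster-based permutation analysis (CPA).**  Per bin, a two-sided paired
t-test compares a condition's participant-level (trial-averaged) fixation
proportion with the unrelated distractor's, at cluster-forming α = 0.05.
Runs of ≥2 adjacent same-sign supra-threshold bins form clusters scored by
Σt.  The null distribution flips each participant's condition/unrelated
labels independently (sign flips of the difference series — exact for the
paired design) and takes the maximum |Σt| per permutation (the standard
family-wise construction); 1000 permutations by default, and
p = (1 + #{null ≥ |Σt|}) / (n_perm + 1) so p is never zero.  Bins with
zero within-pair variance have no defined t and are excluded from
clustering with a logged warning.

**Growth-curve analysis (GCA).**  The response is the log-gaze proportion
ratio `log(target_occ + 0.5) − log(unrelated_occ + 0.5)` per bin, at trial
level by default (binary occupancies; the model carries random intercepts
for both participants and trials, which only makes sense with trial-level
data), with a participant-level-proportion variant available.  Fixed
effects: orthonormal polynomial time terms of order 1..k over the 50 bin
centres (QR-based Gram–Schmidt, zero-mean unit-norm columns, signs fixed
against the raw powers), group (NT reference), their interactions, and
optional standardized participant-level covariates.  Final estimates use
REML; order selection compares maximum-likelihood fits of successive
orders by likelihood-ratio tests (2 df per added order with two groups),
stopping at the first non-significant addition.  The default order is 4
(quartic).  Wald p-values use a between-within df split: terms constant
within participant (intercept, group, covariates) are tested on
participant-level df, time-varying terms on residual df.  This choice is
recorded in every output; pure residual df measurably inflated the
group-term type-I rate in simulation (≈13% at 16 participants), while the
between-within split is calibrated (≈5%).  If the optimizer stalls on a
zero-variance boundary the fit is retried with a slower, boundary-robust
optimizer, and a variance component estimated at zero with failed
convergence is dropped with a flag.

**Divergence-point analysis (DPA).**  Within 750–2500 ms, a one-sided
paired t-test (target > agent-related) per bin at α = 0.05; the group
onset is the start of the first run of ≥K consecutive significant bins
(K = 4, i.e. 200 ms of sustained divergence; configurable and recorded in
all outputs).  1000 bootstrap iterations resample participants with
replacement within group; the group estimate is the mean of bootstrap
onsets with a 95% percentile interval, and the paired per-iteration
difference gives the group comparison with a proportion-based two-sided
p = 2·min(P(d≤0), P(d≥0)) with a +1 correction.  Iterations without a
sustained run are recorded as missing; above 10% missing a warning is
attached.  Both the bootstrap mean and the original-sample onset are
reported, since either convention appears in the literature.  Note that
percentile intervals over onset distributions quantized to 50-ms bins are
conservative: in simulation at the default settings their coverage of a
true 150-ms group shift is essentially 100%, and the difference test is
correspondingly low-powered.  Users who need calibrated CIs at small
effect sizes should treat the interval as an upper bound on uncertainty.

**Individual indices and correlations.**  Per participant: the log-ratio
index (mean log-gaze proportion ratio over bins fully inside the 0–1300-ms
prediction window, i.e. bins 0–25 — the bin starting at patient onset is
excluded) and the individual divergence point (same run criterion as DPA,
applied to the participant's own across-trial proportions; undefined —
never a sentinel — when no run exists, and removed pairwise downstream).
Pearson correlations with Fisher-z 95% CIs relate these indices to CARS
(autistic group only, mirroring its administration) and to AQ total and
its five subscales per group; Benjamini–Hochberg FDR is applied within
each family of five subscales (one family per group × index — the
narrowest reading of a subscale-wise correction), and each output row
records its family.

**Behavioral accuracy.**  A logistic mixed model
`correct ~ group + (1|participant) + (1|trial)` fitted by a Laplace
approximation around the joint mode (the `nAGQ=0` flavour of the standard
GLMM Laplace fit), implemented in `vwpgaze.glmm` with Wald SEs from the
fixed-effect block of the inverse joint Hessian.  A variational-Bayes
alternative was rejected after measurement: its posterior SDs
underestimated the sampling variability of the group coefficient by
roughly half, while the Laplace fit is calibrated (empirical SD 0.196 vs
mean SE 0.201 in simulation) and agrees with an independent reference
implementation to ~0.03 on the coefficient and 3 decimals on SEs and
variance components (cross-checked in the test suite).  Complete
separation (a group with all-identical outcomes) is detected, flagged, and
handled with a ridge penalty (Gaussian, SD 5 log-odds) so the estimate is
finite and never silent.

## Synthetic-data generator

The generator emulates the study conditions: 45 autistic and 52 NT
participants, 24 trials each, 120-Hz binocular gaze on a 1920×1080 screen
with four 384×384 AOIs.  Each trial's latent gaze state follows a
time-inhomogeneous categorical process over the four AOIs plus an explicit
off-AOI background state that absorbs residual probability.  Three phases:
all AOIs start at a common level (0.12); an agent-onset logistic ramp
(midpoint 800 ms, scale 140 ms) raises target and agent-related occupancy
to 0.22; after the verb a second logistic ramp — midpoint
`onset_latency_ms` after verb onset — carries the target to its asymptotic
bias while the agent-related AOI decays to a floor (0.10), and the
action-related AOI receives a transient Gaussian bump (peak +0.06 near
1700 ms), reproducing the incremental-processing signature in which
verb-compatible but agent-incompatible items transiently attract gaze.

Group defaults (NT: midpoint latency 775 ms, bias 0.54; autistic: 902 ms
... realized as 866 ms after accounting for the weaker bias, bias 0.46;
both slopes 80 ms) were derived analytically so that the *emergent*
detected divergence points and cluster windows land near the reported
group phenomenology (divergence ≈1316/1443 ms, difference ≈127 ms, target
clusters from ≈900 ms to the window end with a larger NT cluster mass);
between-participant SDs are 80 ms (latency) and 0.035 (bias).  A
participant's latency deviation shifts both ramps (a shared timing trait)
and their bias scales both plateau elevations, so individual differences
are visible in the prediction window and not only after the verb ramp.

The latent state is redrawn on a 150-ms grid whose phase is jittered per
trial in 50-ms steps: dwells of ≥150 ms survive the minimum-duration
filter even after velocity-classification trims a sample or two at each
transition, bin alignment is preserved (so, with noise off, the
preprocessed tensor equals the latent occupancy *exactly* — a key
end-to-end test), and the jitter prevents all trials from sharing
segment boundaries, which would quantize group-average curves to the dwell
grid.  Gaze points are the AOI centre plus a per-dwell jitter (SD 35 px)
and per-sample, per-eye tremor (SD 2 px, far below the velocity
threshold); blinks arrive at 0.15 Hz with uniform 50–300-ms durations,
deliberately bracketing the 75-ms interpolation limit so both branches of
the gap rule are exercised.

Scores are linear functions of the participant's standardized latency and
bias plus Gaussian noise: CARS (autistic group only) and five AQ subscales
whose sum is the AQ total, with group means and spreads chosen to match
the study's demographic table and link coefficients sized to yield
index-score correlations of roughly 0.3–0.5 magnitude at the latent level
(communication carrying the strongest link).  Behavioral correctness is
Bernoulli per trial with group base accuracies 93.4%/95.9%, participant
heterogeneity of 1.3 log-odds (the base logit is inflated by the
logit-normal attenuation factor so the *marginal* group means match), and
a weak coupling to the latent parameters.

A latent-occupancy fast path (`simulate_cohort_tensor`) samples the same
categorical process directly per bin, skipping the gaze-sample and
fixation-detection layers; large simulation studies (type-I calibration
over 500 cohorts, divergence coverage over 100 study-scale replicates) use
it for speed, while the full gaze path is exercised end-to-end in the
recovery and pipeline tests.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: saccade kinematics (transitions are
instantaneous jumps), smooth pursuit, drift and calibration error,
realistic track-loss clustering (blinks are the only loss process),
pupillometry, and any dependence of gaze on the specific words or images.
Correlation magnitudes between indices and scores are conservative
relative to the study's reported values because the binary-occupancy noise
at 24 trials dilutes the latent signal.

## Reproducibility

Every sampler takes an explicit seed; `(spec, seed)` reproduces cohorts
byte-identically through the text round-trip (`%.17g` formatting with
round-trip float parsing).  The pipeline derives per-stage seeds from one
master seed via `SeedSequence(master, spawn_key=(stage_index,))`, so
stages can be re-run in isolation; the run manifest records the config
verbatim, all derived seeds, and every under-specified default in effect
(velocity threshold, run length K, df method, FDR family, aggregation
level).  Statistical results are invariant to participant order:
participants are sorted internally before any seeded resampling.

## Problem sizes used in the test suite

Simulation studies are sized for desk-scale runs: GCA recovery/type-I use
cohorts of 8 per group × 12 trials (400 mixed-model fits), CPA type-I uses
500 cohorts of 20 participants with 1000 permutations each, and DPA
recovery uses 100 study-scale (45/52) cohorts with 1000 bootstrap
iterations, all through the latent fast path.  The acceptance script runs
the full gaze path once at study scale, including the trial-level GCA on
116,400 observations.

## Known limitations

- The Laplace GLMM is a minimal engine (binomial/logit, random intercepts
  only), not a general mixed-model package.
- DPA percentile intervals are conservative at 50-ms onset resolution (see
  above); the group-difference test correspondingly sacrifices power.
- The GCA Wald p-values rest on a df approximation; no
  Satterthwaite/Kenward–Roger machinery is provided.
- Native eye-tracker exports (EDF/IDF, vendor TSV dialects) are supported
  only through the documented column-mapping hook, not parsed natively.
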