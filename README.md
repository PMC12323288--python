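# vwpgaze

Analysis pipeline for visual-world-paradigm (VWP) eye-tracking studies of
predictive language processing, built for two-group child studies (an
autistic and a neurotypical group) listening to subject–verb–object
sentences while viewing four-image arrays.

In this paradigm each trial shows a target (the sentence-final patient),
an agent-related distractor, an action-related distractor and an unrelated
distractor while a sentence like *"The bird eats the worm"* unfolds
(agent at 0 ms, verb at 750 ms, patient at 1300 ms).  Where listeners look
before the patient word reveals whether, and how fast, they integrate
agent and verb information to predict it.  The package provides:

- **Stimulus construction**: sentence quadruplets cross-pairing two agents
  and two actions, fully balanced (each word serves each condition once;
  each condition occupies each screen position once) with constrained
  pseudo-randomization.
- **Synthetic gaze generation**: a two-group, 120-Hz binocular gaze
  simulator with known ground-truth prediction parameters (group-specific
  onset latency and target bias), blink gaps, measurement noise, and score
  tables (CARS, AQ and subscales) linked to the latent parameters — so the
  whole pipeline is testable without recorded data.
- **I-VT preprocessing**: gap interpolation (≤75 ms), binocular averaging,
  velocity-threshold fixation classification (30°/s), conjunctive merging
  (≤75 ms and ≤0.5°), 100-ms minimum duration; 384×384-px AOIs; binary
  coding into 50-ms bins over 0–2500 ms.
- **Cluster-based permutation analysis (CPA)**: per-bin paired t-tests vs
  the unrelated distractor, Σt cluster mass, sign-flip permutation null
  (1000 permutations, max-statistic correction).
- **Growth-curve analysis (GCA)**: linear mixed model of the log-gaze
  proportion ratio log((target + 0.5)/(unrelated + 0.5)) on orthogonal
  time polynomials × group, random intercepts for participants and trials
  (NT reference), with likelihood-ratio order selection.
- **Divergence-point analysis (DPA)**: bootstrap estimation (1000
  iterations, participant resampling) of the onset of sustained
  target-over-agent-related looking per group, and of the group difference.
- **Individual differences**: per-participant log-ratio index (0–1300 ms)
  and divergence point, Pearson correlations with CARS/AQ (FDR over the
  five AQ subscales), and a logistic mixed model for behavioral accuracy.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate a small cohort, preprocess it, and time the group divergence:

```python
import numpy as np
from vwpgaze import (CohortSpec, simulate_cohort, preprocess_cohort,
                     bootstrap_divergence, permutation_test)

spec = CohortSpec(n_per_group={"autistic": 20, "NT": 20}, seed=3)
cohort = simulate_cohort(spec)
tensor = preprocess_cohort(list(cohort.gaze.values()), cohort.designs)

_, clusters, _ = permutation_test(tensor, "target", "NT",
                                  n_perm=1000, seed=0)
c = max(clusters, key=lambda c: abs(c.sum_t))
print(f"NT target vs unrelated: {c.start_ms:.0f}-{c.end_ms:.0f} ms, "
      f"sum_t={c.sum_t:.1f}, p={c.p:.4f}")

results, diff = bootstrap_divergence(tensor, groups=("autistic", "NT"),
                                     n_boot=1000, seed=1)
for g, r in results.items():
    print(f"{g}: divergence {r.dp_estimate_ms:.1f} ms, "
          f"95% CI [{r.ci95[0]:.0f}, {r.ci95[1]:.0f}]")
print(f"difference (NT - autistic): {diff.difference_ms:.1f} ms, "
      f"p={diff.p:.3f}")
```

Output:

```
NT target vs unrelated: 950-2500 ms, sum_t=300.1, p=0.0010
autistic: divergence 1418.3 ms, 95% CI [1250, 1500]
NT: divergence 1169.2 ms, 95% CI [900, 1500]
difference (NT - autistic): -249.2 ms, p=0.440
```

The NT group shows sustained preferential looking at the target from
about 200 ms after verb onset through the end of the trial (the
permutation p is bounded below by 1/1001), and its divergence point — the
onset of sustained target-over-agent-related looking — precedes the
autistic group's here by about 250 ms, against a simulated ground-truth
ramp-midpoint gap of 127 ms.  At n = 20 per group the bootstrap difference
test does not reach significance; the percentile intervals of divergence
onsets (quantized to 50-ms bins) are conservative.

The same chain is available from the shell:

```bash
vwp-gaze simulate --out data/ --seed 3
vwp-gaze preprocess --gaze data/gaze --designs data/designs.csv \
    --scores data/scores.csv --out tensor.csv
vwp-gaze dpa --tensor tensor.csv --n-boot 1000 --seed 1 --out-dir results/
vwp-gaze run --config run.yaml --out results/   # full pipeline, one seed
```

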