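# facereloc

A tested, reusable pipeline for touchscreen **face identity–location
binding** experiments: generate constrained encoding layouts and
counterbalanced trial designs, simulate relocation responses and encoding
scanpaths under an explicit generative model, score trials with the
safe-area accuracy / precision / swap-error procedure, extract oculomotor
measures (fixation, visit, selection and exit order), and run mixed-model
or permutation inference — all exercisable on synthetic data with no
downloads.

## The task and its measures

Participants encode 1–4 expressive faces at pseudorandom positions inside a
central presentation area (42.53° × 26.81° of visual angle), then, after a
blank maintenance interval, drag a single neutral test face back to its
original position. Layouts obey two geometric rules: every face edge lies
at least 7° from the screen center, and face centers are at least 14° apart
— which makes the 7°-radius "safe areas" around encoded locations disjoint.

Each trial is scored as:

- **correct** — the touch lands within 7° of the test face's original
  center (its safe area); **precision** is the residual distance *d* (often
  analysed as ln *d*);
- **swap (mis-binding) error** — the touch lands in another encoded face's
  safe area;
- **random error** — the touch lands in no safe area.

The synthetic generator draws the touch from a three-component mixture.
With binding probability

```
p_bind = logistic(β₀ + β_emotion·1[happy] + β_load·(load − 2)
                  + β_MI·ln(maintenance_s) + (β_recency
                  + β_emotion×recency·1[happy])·1[exited last])
```

the response is the target center plus isotropic Gaussian noise
N(0, σ²_target I); otherwise it is a swapped face center plus noise (with
probability `p_swap_given_error`) or uniform over the presentation area.
Because the target component is an isotropic bivariate Gaussian, the
fraction of target-branch responses captured by the safe area is
`c = 1 − exp(−r²/2σ²)` in closed form, which the package uses both to test
itself and to invert observed correct/swap/random proportions back into
generative mixture weights (`facereloc.stats.recover_mixture`).

Encoding scanpaths are simulated as face visits in random order with
Poisson revisits and log-normal fixation durations; the **exit order** of
the test face (whether it was the last face fixated) feeds back into
`p_bind`, so recency effects propagate through the gaze → scoring → stats
chain by construction.

## Worked example

```python
import numpy as np
from facereloc import (ExperimentConfig, SimParams, build_design,
                       simulate_dataset, apply_exclusions, score_dataset,
                       summarize_performance)
from facereloc.gaze import gaze_table
from facereloc.stats import fit_mixed_model, estimate_sigma

design = build_design(ExperimentConfig.experiment_1(), np.random.default_rng(7))
data = simulate_dataset(design, 12, SimParams(), np.random.default_rng(1))
kept, report = apply_exclusions(data)
print(f"excluded {report.n_removed}/{report.n_total} trials "
      f"({report.pct_total:.1f}%)")
scored = score_dataset(kept)
print(summarize_performance(scored, by=["emotion"])
      [["emotion", "accuracy", "mean_distance_deg", "swap_share"]].round(3))
sigma = estimate_sigma(scored.loc[scored.error_type == "correct",
                                  "distance_deg"])
print(f"estimated relocation noise SD: {sigma:.2f} deg")

gaze = gaze_table(kept)
recency = gaze[gaze.is_test_face][["participant_id", "trial_id",
                                   "exited_last"]]
analysis = scored.merge(recency, on=["participant_id", "trial_id"],
                        how="left")
analysis = analysis[analysis["load"] >= 2].copy()
analysis["acc"] = analysis["correct"].astype(int)
analysis["exited_last"] = analysis["exited_last"].fillna(False).astype(float)
fit = fit_mixed_model(analysis, "acc", ["emotion", "load", "exited_last"],
                      random={"participant_id": ["1"], "trial_id": ["1"]})
print(fit.to_frame().round(3))
```

Output:

```
excluded 144/3072 trials (4.7%)
  emotion  accuracy  mean_distance_deg  swap_share
0   angry     0.795              2.481       0.769
1   happy     0.838              2.421       0.728
estimated relocation noise SD: 1.94 deg
                   term   beta     se    stat  p_value
0             Intercept  1.943  0.054  35.986    0.000
1  emotion[happy-angry]  0.362  0.108   3.352    0.001
2                  load -0.241  0.017 -14.367    0.000
3           exited_last  0.634  0.105   6.028    0.000
```

Reading the output: 4.7% of trials fell to the four eye-tracking exclusion
rules; relocation accuracy is higher for happy than angry displays (the
generative emotion shift is positive); the fitted noise SD of 1.94°
recovers the generative σ_target = 2°; and the binomial mixed model finds
positive emotion and recency (exited-last) coefficients and a negative load
coefficient, matching the simulation's generative directions.

A command-line interface mirrors the library
(`facereloc generate-design | simulate | score | gaze | fit | recover`);
see `facereloc --help`.

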