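# Methods

This note documents the models, defaults and numerical choices behind
`facereloc`, in the spirit of a statistical package's methods appendix.
Nothing here reports an empirical result; every quantitative claim below is
recomputed by the test suite or by `scripts/acceptance.py`.

## Coordinate system and geometry

All spatial quantities are degrees of visual angle, origin at the screen
center, x rightward, y upward. Physical extents convert by the linear
small-angle rule θ = (s/d)·(180/π) with viewing distance d = 40 cm; this is
the convention under which the default display constants are exact (a
50.9 cm screen width ↔ 72.91°, the 1120 × 706 px presentation area ↔
42.53° × 26.81°). Pixel extents convert through the axis-specific pixel
pitch of the 1920 × 1080 / 50.9 × 28.7 cm panel. Face stimuli are ovals
with half-extents 1.85° × 2.595° (taken from the printed 3.70° × 5.19°
size, which is treated as authoritative over re-deriving it from the
printed cm size — the two disagree at the second decimal).

## Layout sampling

Encoding layouts are drawn by uniform rejection sampling of face centers
over the presentation area (shrunk so whole faces fit), subject to:

1. **edge rule** — the distance from the screen center to the face's
   bounding-ellipse edge, measured along the connecting line, is ≥ 7°.
   The ellipse radius along direction u is ab/√((b·uₓ)² + (a·u_y)²);
2. **pairwise rule** — face centers are ≥ 14° apart.

A partial layout that blocks completion for 500 consecutive draws is
restarted; 10,000 total draws without success raises an error naming the
most-violated rule (constraints are never silently relaxed). A cheap
necessary-condition check (pairwise minimum vs. the center-region diagonal)
rejects plainly impossible configurations up front. Because 14° = 2 × 7°,
safe areas of distinct faces are disjoint, which makes the correct / swap /
random classification a partition.

## Trial designs

Experiment 1 crosses load (1–4) × emotion (angry/happy) at a 1-s
maintenance interval; Experiment 2 fixes load 4 and crosses maintenance
interval (1/3/6 s) × emotion. The default 32 trials per cell gives 256 and
192 trials. Encoding lasts 1.5 s per face. Within each cell, identity
assignment uses a least-used round-robin over the 8 identities, which
guarantees per-cell appearance counts differ by ≤ 1; the tested identity is
additionally balanced by a least-used-as-test counter. The screen half
containing the test face is counterbalanced exactly (half left, half
right), mirroring a sampled layout when necessary — mirroring preserves
both layout rules. Counterbalancing versions are plain left/right
reversals of a base design generated from the same seed; no claim is made
to reconstruct any particular historical 12-version scheme, whose exact
factor structure is not fully specifiable from the task description.
`reps_per_cell` must be even (side counterbalancing), else a configuration
error is raised.

## Generative model for responses

Each trial's touch is drawn from a three-component mixture. The binding
probability is

p_bind = logistic(β₀ + β_em·1[happy] + β_load·(load − 2) + β_MI·ln(MI_s)
         + (β_rec + β_em×rec·1[happy])·1[exited last]),

and the response is the target center + isotropic Gaussian noise
(σ_target) with probability p_bind; otherwise a uniformly chosen non-target
center + noise (σ_swap) with probability p_swap|error (single-face displays
force the uniform branch); otherwise uniform over the presentation area.
Out-of-area draws are **clipped** to the area rather than resampled, so
mixture weights are preserved exactly.

Defaults (all artifact calibration choices, not empirical estimates):

| parameter | default | rationale |
| --- | --- | --- |
| β₀ | 1.4 | angry, load-2, 1-s, non-recent binding logit ≈ 0.80 |
| β_em | 0.25 | happy accuracy advantage of a few points |
| β_load | −0.35 /face | accuracy declines with load |
| β_MI | −0.27 /ln s | accuracy declines with maintenance interval |
| β_rec | 0.5 | exited-last (recency) advantage |
| β_em×rec | 0.25 | happy benefit concentrated at the last exit |
| σ_target | 2.0° | correct-trial precision ≈ 2.5° mean distance |
| σ_swap | 2.5° | swap relocations slightly less precise than correct |
| p_swap\|error | 0.85 | swap share of multi-face errors ≈ 0.8–0.9 |

Together these put aggregate accuracy in the ≈ 0.73–0.85 range and the
swap share of multi-face errors around 0.8–0.9, the regimes the scoring
and inference stages are designed for. The noise law is isotropic (no
angular bias) because only radial precision is analysed.

A useful closed form: the target component's probability of landing within
the safe radius r is c = 1 − exp(−r²/2σ²). Clipping cannot alter this
capture probability whenever the target's safe disc lies entirely inside
the presentation area (a clipped point lies on the boundary, hence ≥ r from
such a target); the radial-law checks therefore condition on interior-disc
targets, where the law holds to Monte-Carlo error at every σ tested.

## Generative model for scanpaths

A scanpath is a sequence of face visits: one first pass in random order
plus Poisson(revisit_rate) extra entries per face, shuffled (adjacent
duplicates collapse into one visit); optionally one face is skipped with
p_skip. Each visit holds 1–3 fixations with log-normal durations
(arithmetic mean `mean_fix_ms` = 310 ms, log-SD 0.3, giving mean visits
around 600 ms), separated by 30-ms saccade gaps, truncated at encoding
offset. Gaze points are uniform within the visited face's bounding
rectangle. The test face's recency flag (`exited_last`) is computed **from
the simulated scanpath** and fed into p_bind, so exit-order effects
downstream are reproducible by construction; recency is defined only for
multi-face displays. Per-trial calibration fields and a pre-trial central
fixation are drawn so that configured fractions of trials
(defaults 0.007 / 0.014 / 0.023) violate the calibration, pre-check and
start-fixation exclusion rules.

What the generator does *not* emulate: saccade dynamics and raw-sample
parsing (it emits already-parsed fixations), drag trajectories and response
times, participant- and item-level heterogeneity (no random effects in the
generative model; the inference layer still estimates them), and any visual
properties of faces beyond identity/expression labels. Passing tests on
this synthetic data therefore validates the *pipeline's arithmetic and
inferential calibration*, not claims about human behavior.

## Scoring

Exclusions apply sequentially, each on the trials surviving the previous
rule, with percentages reported against the then-remaining data: (1) mean
calibration error ≥ 0.5° or any calibration point ≥ 1° (inclusive ≥);
(2) pre-trial check error ≥ 1°; (3) first fixation of the trial > 7° from
the screen center; (4) test face never fixated during encoding (any
encoding-window fixation inside its ROI + 0.5° margin counts).

Classification uses the inclusive boundary (distance exactly 7° is
correct/swap — "within" is read inclusively; the boundary has measure
zero, and inclusivity makes the rule deterministic). On the measure-zero
tangent point equidistant from two centers, the test face wins if it is one
of them, otherwise the lowest face slot. Precision logs are natural logs;
a zero distance (possible only with degenerate noise) is replaced by half
the smallest positive observed distance before averaging logs. An
unconstrained accuracy variant (`nearest_is_target`: whichever original
center is closest, no radius) is computed alongside.

`recover_mixture` inverts the observed (correct, swap, random) proportions
through the linear mixing matrix built from c = 1 − exp(−r²/2σ̂²) and the
uniform component's safe-area leakage a = πr²/A (A = presentation-area
size): q_correct = c·w_t + a·w_u, q_swap = c·w_s + (k−1)a·w_u, with the
remainder random. Estimates are clipped to [0, 1] and renormalized; σ̂ → ∞
(c ≈ 0) raises an unidentifiability error. Note that even at σ̂ = 0 the
inversion differs from the raw proportions whenever w_u > 0, because
uniform touches land inside safe areas with non-trivial probability
(a ≈ 0.135 by default); the inversion, not the raw proportions, recovers
the generative weights. σ̂ itself is estimated from correct-trial
distances by maximum likelihood under a two-component density on (0, r]:
a radius-truncated Rayleigh (target) plus a uniform-over-disc contaminant,
optimized with Nelder–Mead on (log σ, logit w).

## Gaze measures

A face's ROI is the smallest axis-aligned rectangle enclosing its oval,
expanded 0.5° on all sides (inclusive). A visit is a maximal run of
consecutive same-face fixations; off-face fixations shorter than 80 ms are
transparent to run segmentation (they neither join nor break a visit),
while longer ones end it — the 80-ms micro-gap tolerance is configurable
and documented here because the underlying task description is silent on
it. Visit duration sums the visit's fixation durations (saccade gaps
excluded). Fixations starting before display onset or ending after offset
are excluded from mean fixation/visit durations but retained for order
computation. Selection rank orders faces by first-visit start, exit rank
by last-visit end (end time adopted; ranking by last-fixation onset would
differ only within a single fixation). Timestamp ties break by face slot.
Order analyses flag trials unusable when not all faces were fixated or
every face received exactly one visit (selection ≡ exit). Kendall's τ-b
with tie correction tests the selection–exit association, using the exact
null distribution below n = 10 (untied) and the normal approximation
otherwise.

## Inference

Sliding (repeated/backward-difference) contrasts estimate adjacent
level-mean differences; simple contrasts compare each level to the first,
centered. Both codings have zero-sum, full-rank columns and reduce to
(−½, +½) at two levels.

`fit_mixed_model` fits binomial or gaussian mixed models with uncorrelated
random intercepts and slopes for participants and trial items. Gaussian
models use `statsmodels.MixedLM` (crossed random effects via variance
components on a single dummy group; REML, L-BFGS); binomial models use the
variational-Bayes `BinomialBayesMixedGLM`, whose posterior means/SDs are
reported as β/SE (verified unbiased against a plain GLM on data without
random effects). Convergence means optimizer success with finite,
positive SEs; singular (boundary) variance estimates still count as
converged, as in common lme4 practice. On failure the simplification
ladder drops the highest-order random slope first and simplifies trial
terms before participant terms, logging each step; the terminal rung is a
fixed-effects GLM/OLS with participant-clustered robust SEs. The most
complex converging model is returned. Gaussian p-values use the normal
approximation on t (no Satterthwaite facility is available in the backend);
with the trial counts this package targets (≥ hundreds of observations)
the difference is negligible.

`permutation_inference` is the backend-free alternative for two-level
within-participant factors: the statistic is the mean participant-level
difference, the null flips each participant's sign, and the two-sided
p-value is (1 + #{|null| ≥ |obs|})/(1 + n_perm) — exact under the
exchangeability of signs, with minimum attainable p = 1/(1 + n_perm).

## Problem sizes in the test suite

The suite validates at sizes chosen to balance statistical resolution
against a desk-scale run: 500–1,000 layouts for geometric guarantees;
10,000 points for the scoring oracle and radial law; 20 replicates of the
full 48-participant × 256-trial design for parameter recovery (emotion
coefficient within ±0.1, σ within ±0.1°, mixture weights within ±0.02);
200 null replicates for permutation calibration; 10 replicates of a
24 × 32 load-4 design for the recency round trip. The whole suite runs in
a few minutes on one CPU.

## Known limitations

- The generative model is a calibration device, not a cognitive theory:
  its defaults must never be quoted as empirical findings.
- Binomial mixed models are variational; posterior SDs can be mildly
  optimistic relative to Laplace/REML standard errors, which matters for
  borderline p-values but not for the parameter-recovery use case.
- The mixture inversion assumes the swap component never leaks into the
  target's safe area (exact when pairwise distances ≥ 2r and σ ≪ r;
  leakage is < 10⁻³ at the default σ).
- Crossed gaussian random effects via a single-group variance component
  formulation scale poorly beyond a few hundred items.
- Identity counterbalancing guarantees the ≤ 1 appearance-count bound per
  cell but does not reproduce any specific published version scheme.
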