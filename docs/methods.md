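# Methods

This note documents the models, assumptions, parameter defaults, numerical
choices and limitations of `swlplan`. All empirical statements here are
checked by the test suite (`tests/`) or recomputed by
`scripts/acceptance.py`; nothing below is quoted from an external dataset.

## Problem

A shock wave lithotripsy (SWL) treatment plan is an ordered sequence of
steps, each a triple *(power level, shock rate, number of shocks)* with
power level in 1–9, shock rate in {60, 90, 120, 180}/min, and a positive
shock count. A session is bounded by a 3000-shock budget. The package
learns to generate the next step from the steps delivered so far plus
preoperative patient characteristics (PPC), and to synthesize complete plans
autoregressively under the budget.

## Case normalization and decomposition

Raw delivery records are normalized in two passes
(`swlplan.cases.normalize_plan`):

1. **Merge** consecutive records with identical (power, rate) into one block.
2. **Split** any merged block of more than 1000 shocks into consecutive
   1000-shock steps plus a remainder. A block of exactly 1000 is left alone.

Total shocks and ordering are conserved; each resulting step has at most
1000 shocks. Worked example: seven 100-shock records at powers 1–7 followed
by 2300 shocks at power 8 normalize to ten steps, the final block becoming
1000 + 1000 + 300.

An *n*-step plan is decomposed exhaustively into *n − 1* supervised samples:
(first *i* steps, PPC) → step *i + 1*, for *i* = 1 … *n − 1*
(`decompose_case`). Single-step plans yield no samples and raise a warning.
The train/validation split is at the **case** level (greedy assignment of
whole cases toward the target sample fraction, default 10% validation), so
no case contributes samples to both sides.

## Representations

- **Step encoding** (width 14): one-hot power level (9) + one-hot shock rate
  (4) + count / 1000. Exactly invertible for valid steps. The 1000 scale
  matches the per-step cap, keeping the regression target in (0, 1].
- **PPC vector** (width 12): gender, age, stone size (mm), mean arterial
  pressure, anticoagulant use, sedation, multiple stones, strapping, plus a
  4-way one-hot stone location (renal pelvis, upper/middle/lower calyx). The
  three continuous fields are z-scored with statistics fitted on the
  training split only.

## Step-generation model

An LSTM encodes the variable-length step prefix into its final hidden state
(gate order i, f, g, o; zero initial state, so an empty prefix encodes to
the zero vector). The state is concatenated with the PPC vector and passed
through two fully connected ReLU layers; task heads emit a softmax
distribution over the 9 power levels, a softmax over the 4 rates, and a ReLU
scalar for the scaled count. Classification heads train with categorical
cross-entropy, the count head with MSE on the count/1000 scale; the
optimizer is Adam. By default the three tasks are trained as three separate
networks sharing the architecture template (`shared_trunk=True` trains one
three-headed network instead).

The implementation is plain numpy with explicit backpropagation through
time. The model is small (hidden width 64, a few thousand samples), so
numpy training takes a few minutes on one CPU; in exchange the recurrence is
fully controlled, single-threaded deterministic, and testable against an
independently coded gate-recurrence oracle.

**Training defaults** (`TrainConfig`): hidden width 64, FC widths (64, 32),
Adam learning rate 1e-3, batch size 64, up to 600 epochs, early stopping on
validation loss with patience 100, and a plateau schedule that halves the
learning rate after every `patience // 3` epochs without improvement. The
parameters with the best validation loss are kept. These values were chosen
so the count head — the slowest task to converge — fits the piecewise-
constant count policy of the default simulator; they were frozen before the
acceptance thresholds were evaluated. Glorot-uniform weight initialization,
zero biases. All randomness flows from seeded `numpy` generators.

**Decoding** (`predict_step`): argmax over each softmax head (lowest-index
tie-break, i.e. lower power / slower rate), count rescaled to shocks,
rounded, and clamped to [1, 1000].

## Synthetic registry

Real SWL registries are proprietary, so training and evaluation run on a
documented simulator (`swlplan.registry`). **The defaults below are the
study conditions** used by the acceptance tests and `scripts/acceptance.py`.

**PPC population** (`PPC_DISTRIBUTIONS`): age ~ truncated normal (52, 14) on
[18, 90]; stone size ~ log-normal with median 8 mm (log-sd 0.35); mean
arterial pressure ~ truncated normal (95, 10) on [60, 140]; stone location
categorical (0.25, 0.20, 0.30, 0.25); gender/anticoagulant/sedation/multiple
stones/strapping Bernoulli (0.5, 0.15, 0.5, 0.2, 0.3). Exact distribution
means are exposed for calibration tests (`ppc_distribution_means`).

**Policy** (`PolicyParams`, defaults in parentheses):

- Plans start at power level 1 and ramp one level per block. The
  per-patient ramp block is `200 + 4·(MAP − 95)` shocks, rounded to tens and
  clamped to [100, 350] — better-perfused patients tolerate faster
  escalation.
- The maximum power is `round(7 + 0.25·(size − 8) + 0.03·(MAP − 95))`
  clamped to [1, 9]: larger stones need more energy.
- The rate rule (`ppc_default`): 60/min under anticoagulation, 90/min at age
  ≥ 65, 180/min for small stones (< 6 mm) in patients under 40, else
  120/min.
- At maximum power the plan delivers 400-shock hold blocks, alternating
  between the chosen rate and the adjacent slower rate (a pacing pattern
  that also keeps sub-1000-shock hold steps distinct under normalization).
  After each at-max block the treatment ends with probability
  `0.30 − 0.03·(size − 8)` (clamped to [0, 1]); larger stones fragment more
  slowly, so plan length increases with stone size.
- If the stone has not fragmented after 3 hold blocks, power escalates one
  level per step toward 9 (`boost_after_holds=3`).
- The session never exceeds `shock_limit` (3000) total shocks.
- `noise_level` (default 0) optionally perturbs steps (adjacent-rate jitter
  or a skipped ramp level) to emulate practice variation.

With `noise_level = 0` every emitted step is a deterministic function of
(PPC, steps so far); randomness enters only through the stopping draw, which
decides whether a next step exists. A sequence model can therefore recover
the policy, which is the basis of the acceptance experiment. Three policy
components are deliberately hard for flattened (averages + last step + PPC)
features: the hold-block count that triggers escalation (an integer position
in the sequence), the oblique size-and-MAP maximum-power boundary, and the
continuous MAP-dependent ramp block.

**What the simulator does and does not emulate.** It emulates the shape of
expert ramping practice: monotone power escalation, PPC-dependent rates and
maxima, a hold phase, stochastic termination, and the session budget. It
does **not** reproduce any real registry's distributions, success-rate case
selection, clinical fragmentation assessment, or cross-device differences;
absolute performance numbers on synthetic data are not comparable to numbers
on clinical data. Default plans run about 6–13 normalized steps.

## Baselines

Classical models see flattened features: averages of (power, rate, count)
over the prefix, the last step verbatim, and the PPC vector. Classifiers
(logistic regression, random forest with 200 trees, RBF-kernel SVC — the
latter two exactly as shipped by scikit-learn) predict power and rate;
regressors (linear regression, random forest, RBF SVR) predict the count.
Features are standardized for the linear/kernel models. Baseline count
predictions are rounded and clamped to [1, 1000] exactly like the deep
model's, so the comparison is fair. Single-class training targets skip the
affected classifier with a warning.

## Evaluation

- **Accuracy**: trace of the confusion matrix over total observations.
- **Macro precision/recall/F1**: unweighted means of per-class values;
  per-class values with a zero denominator count as 0 and the affected
  classes are flagged in the report. Macro F1 is the mean of per-class F1
  scores (not the harmonic mean of macro precision and macro recall).
- **Count errors**: RMSE and MAE on the shock scale.
- **Paired t-test** of generated minus reference values, two-sided p from
  the t distribution. Conventions: all-zero differences → (t = 0, p = 1);
  zero variance with nonzero mean → (t = ±∞, p = 0); a single observation →
  (NaN, NaN).
- **Breakdown by number of previous steps**: the same metrics stratified by
  prefix length.

## Planner

`generate_plan` starts from the empty prefix (zero LSTM state), repeatedly
asks the model for the next step, and stops when the cumulative count
reaches the budget (default 3000); a final step that would overshoot is
truncated to the remaining shocks. Decoding is argmax, so plans are
deterministic given (model, PPC). A `max_steps` guard (50) bounds degenerate
models. The budget invariant — no generated plan exceeds 3000 shocks — is
the package's recomputed acceptance target.

## Reproducibility

One `ExperimentConfig` fully determines an experiment. Its master seed is
split with `numpy.random.SeedSequence.spawn` into per-stage seeds (registry,
split, train, baselines, plans), each reduced modulo 2³¹. Identical configs
reproduce bitwise-identical registries, weights, reports and plans on one
thread (checked by tests).

## Limitations

- All performance claims are about recovery of a *synthetic* policy;
  nothing here validates clinical efficacy or transfers to real registries.
- The generated plan's first step is produced from the empty prefix.
  Training uses only non-empty prefixes by default (mirroring the
  decomposition, which starts at prefix length 1), so first-step behavior is
  an extrapolation; `TrainConfig(include_first_step=True)` adds synthesized
  empty-prefix samples if first-step fidelity matters.
- Autoregressive generation can wander once the prefix grows past the plan
  lengths seen in training (e.g. many tiny steps near the end of a long
  plan); the planner's budget and step-count guards still bound every plan,
  but late-plan step quality is extrapolation.
- The numpy trainer is single-threaded and intentionally small; it is not a
  general-purpose deep learning stack.
- The paired t-test treats per-sample differences as exchangeable; samples
  from the same case are correlated, so p-values are indicative, not
  confirmatory.
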