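# swlplan

Automated treatment planning for shock wave lithotripsy (SWL): a sequence
model that generates the next treatment step — power level (1–9), shock rate
(60/90/120/180 per minute) and number of shocks — from the steps delivered
so far and the patient's preoperative characteristics, plus an
autoregressive planner that synthesizes complete protocols under a
3000-shock session budget.

## The science in one paragraph

Expert SWL practice follows a ramping protocol: start at low power, escalate
stepwise, hold at a stone-dependent maximum, stop when the stone fragments.
`swlplan` frames protocol planning as next-step generation. Treatment
records are normalized into canonical steps (consecutive identical settings
merged, blocks capped at 1000 shocks) and decomposed exhaustively: an
*n*-step plan yields *n − 1* supervised samples, (first *i* steps, patient
characteristics) → step *i + 1*. An LSTM encodes the variable-length prefix;
its final state, concatenated with the patient vector, feeds two fully
connected ReLU layers and three task heads (softmax over 9 power levels,
softmax over 4 rates, ReLU count regressor). Flattened-feature baselines
(logistic/linear regression, random forest, SVM over prefix averages + last
step + patient vector) provide the comparison, evaluated with macro-averaged
precision/recall/F1, RMSE/MAE and paired t-tests. Because real registries
are proprietary, training and evaluation run on a documented synthetic
registry whose noise-free expert policy the model must recover; see
[docs/methods.md](docs/methods.md) for the full model, the simulator's
assumptions, and limitations.

## Worked example

Normalize and decompose the classic ramping case — 100 shocks at each of
power levels 1–7, then 2300 at power 8 (all at 120/min):

```python
from swlplan import PPCVector, decompose_case, normalize_plan

raw = [(p, 120, 100) for p in range(1, 8)] + [(8, 120, 2300)]
plan = normalize_plan(raw)          # 10 steps: the 2300 splits into 1000+1000+300
ppc = PPCVector(gender=1, age=55.0, stone_location="renal_pelvis",
                stone_size=8.0, mean_arterial_pressure=95.0,
                anticoagulant_use=0, sedation_use=1, multiple_stones=0,
                strapping=0)
samples = decompose_case(plan, ppc)  # 9 samples; last target: (8, 120, 300)
```

Run the full experiment — simulate 200 cases, split at the case level
(90/10), train, fit baselines, evaluate, generate plans:

```python
from swlplan import ExperimentConfig, run_experiment
report = run_experiment(ExperimentConfig(n_cases=200, seed=1), "experiment")
```

This is `examples/03_train_and_evaluate.py`; on seed 1 it prints:

```
validation performance (deep model):
  power level: accuracy 1.0000, macro F1 0.8889
  shock rate:  accuracy 1.0000, macro F1 1.0000
  shock count: RMSE 51.3, MAE 37.3

power-level macro F1, deep model vs baselines:
  deep model          0.8889
  logistic_regression 0.8480
  random_forest       0.8848
  svm                 0.8122
```

The deep model recovers the synthetic expert policy essentially exactly on
held-out cases, and its power-level macro F1 exceeds every flattened-feature
baseline — the baselines cannot see the sequence position that triggers
late-treatment power escalation. Plan generation for a new patient
(`examples/04_generate_plan.py`) then produces a complete budget-bounded
protocol, e.g. 26 steps totalling exactly 3000 shocks for an 11 mm
lower-calyx stone.

The other narrative scripts: `examples/01_simulate_registry.py` (simulate
and inspect a registry; on seed 1: 200 cases, 6–13 steps per plan, max total
3000) and `examples/02_decompose_case.py` (the worked example above, with
the full step table printed).

A thin CLI wraps the same library surface:

```bash
swlplan simulate --n-cases 200 --seed 1 --out-dir registry/
swlplan decompose --cases registry/cases.csv --ppc registry/ppc.csv --out samples.jsonl
swlplan train --samples samples.jsonl --out model/
swlplan evaluate --model model/ --samples samples.jsonl --out report.json
swlplan plan --model model/ --ppc patient.json
swlplan run --out-dir experiment/        # the whole pipeline in one command
```

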