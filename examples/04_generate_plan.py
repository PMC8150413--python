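"""Generate a complete treatment plan for a new patient.

Loads the model trained by examples/03_train_and_evaluate.py (run that
first) and synthesizes a plan autoregressively: starting from an empty
sequence, the model proposes the next step, the planner appends it, and
generation stops when the 3000-shock session budget is reached — a final
step that would overshoot is truncated to the remaining shocks.

Run:  python examples/04_generate_plan.py
"""

from pathlib import Path

from swlplan import GeneratorBundle, PlanBudget, PPCVector, generate_plan, render_plan

model_dir = Path("example_experiment/model")
if not model_dir.exists():
    raise SystemExit("train a model first: python examples/03_train_and_evaluate.py")

bundle = GeneratorBundle.load(model_dir)

patient = PPCVector(
    gender=0, age=48.0, stone_location="lower_calyx", stone_size=11.0,
    mean_arterial_pressure=102.0, anticoagulant_use=0, sedation_use=1,
    multiple_stones=0, strapping=1,
)

plan = generate_plan(patient, bundle, PlanBudget(shock_limit=3000),
                     case_id="new_patient")
print(f"patient: {patient.stone_size:.0f} mm stone in the "
      f"{patient.stone_location}, age {patient.age:.0f}")
print(f"generated {plan.n_steps} steps, {plan.total_shocks} shocks total "
      f"(budget 3000)\n")
print(render_plan(plan))
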