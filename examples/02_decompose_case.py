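"""Normalize a raw treatment record and decompose it into next-step samples.

The worked example: a case delivered as 100 shocks at each of power levels
1-7, then 2300 shocks at power 8, all at 120/min.  Normalization splits the
final block into 1000 + 1000 + 300, giving a 10-step plan; exhaustive prefix
decomposition then yields 9 supervised samples of the form
(first i steps, patient characteristics) -> step i+1.

Run:  python examples/02_decompose_case.py
"""

from swlplan import PPCVector, decompose_case, normalize_plan, render_plan

raw_records = [(power, 120, 100) for power in range(1, 8)] + [(8, 120, 2300)]

plan = normalize_plan(raw_records, case_id="worked_example")
print(f"raw records: {len(raw_records)}  ->  normalized steps: {plan.n_steps}")
print(render_plan(plan))

ppc = PPCVector(
    gender=1, age=55.0, stone_location="renal_pelvis", stone_size=8.0,
    mean_arterial_pressure=95.0, anticoagulant_use=0, sedation_use=1,
    multiple_stones=0, strapping=0,
)

samples = decompose_case(plan, ppc)
print(f"\n{len(samples)} next-step samples:")
for s in samples:
    t = s.target
    print(f"  prefix of {s.prefix_length:>2} step(s) -> "
          f"(power {t.power_level}, rate {t.shock_rate}, {t.num_shocks} shocks)")
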