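"""Simulate a synthetic SWL registry and look at what the policy produces.

Real lithotripsy registries are proprietary, so the package ships a
documented simulator of expert ramping practice: plans start at power level
1, ramp one level per block of shocks, hold at a stone-dependent maximum
power, and stop stochastically once fragmentation becomes likely — all under
a 3000-shock session budget.

Run:  python examples/01_simulate_registry.py
"""

import numpy as np

from swlplan import PolicyParams, generate_registry, render_plan

registry = generate_registry(n_cases=200, policy=PolicyParams(), seed=1)

lengths = [plan.n_steps for _, plan in registry.cases]
totals = [plan.total_shocks for _, plan in registry.cases]
print(f"simulated {len(registry.cases)} cases")
print(f"steps per plan: min {min(lengths)}, median {int(np.median(lengths))}, "
      f"max {max(lengths)}")
print(f"total shocks:   min {min(totals)}, max {max(totals)} "
      f"(budget {registry.policy.shock_limit})")

ppc, plan = registry.cases[0]
print(f"\nfirst case ({plan.case_id}): stone {ppc.stone_size:.1f} mm in the "
      f"{ppc.stone_location}, age {ppc.age:.0f}")
print(render_plan(plan))

# persist as the two-table registry format (cases.csv + ppc.csv)
registry.write("example_registry")
print("\nwrote example_registry/cases.csv and example_registry/ppc.csv")
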