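"""Autoregressive treatment-plan synthesis under a session shock budget.

Starting from an empty treatment sequence (the sequence encoder's zero
initial state), the planner repeatedly asks the step-generation model for
the next step, appends it, and stops once the cumulative shock count reaches
the budget.  A final step that would overshoot the budget is truncated to
the remaining shocks — mirroring the clinical requirement to stop at the
limit mid-step.  The emitted plan is guidance: a physician stops earlier if
x-ray confirms fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

from .cases import PPCVector, TreatmentPlan, TreatmentStep, ValidationError


class StepModel(Protocol):
    """Anything that proposes a next step from (prefix, PPC)."""

    def predict_step(self, prefix: Sequence[TreatmentStep], ppc: PPCVector) -> TreatmentStep:
        ...


@dataclass(frozen=True)
class PlanBudget:
    """Session limits: total shock budget and an iteration safety cap."""

    shock_limit: int = 3000
    max_steps: int = 50

    def __post_init__(self) -> None:
        if self.shock_limit < 1:
            raise ValidationError("shock_limit must be >= 1")
        if self.max_steps < 1:
            raise ValidationError("max_steps must be >= 1")


def generate_plan(
    ppc: PPCVector,
    model: StepModel,
    budget: PlanBudget = PlanBudget(),
    case_id: str = "generated",
) -> TreatmentPlan:
    """Iteratively generate steps until the shock budget is exhausted.

    Deterministic for a fixed model and PPC (decoding is argmax, no
    sampling).  The result always totals at most ``budget.shock_limit``
    shocks and has at most ``budget.max_steps`` steps.
    """
    steps: list[TreatmentStep] = []
    total = 0
    while total < budget.shock_limit and len(steps) < budget.max_steps:
        proposed = model.predict_step(tuple(steps), ppc)
        remaining = budget.shock_limit - total
        count = min(proposed.num_shocks, remaining)
        if count < 1:
            break
        step = TreatmentStep(proposed.power_level, proposed.shock_rate, count)
        steps.append(step)
        total += count
    if not steps:
        raise ValidationError("model produced no usable step within the budget")
    return TreatmentPlan(case_id=case_id, steps=tuple(steps))


def render_plan(plan: TreatmentPlan | Sequence[TreatmentStep]) -> str:
    """Human-readable protocol table with cumulative shock totals.

    Accepts a plan or a bare step sequence; an empty sequence renders the
    header only.
    """
    steps = plan.steps if isinstance(plan, TreatmentPlan) else tuple(plan)
    header = (
        f"{'Step':<6}{'Power level':<13}{'Shock rate (/min)':<19}"
        f"{'Shocks':<8}{'Cumulative':<10}"
    )
    lines = [header, "-" * len(header)]
    total = 0
    for k, s in enumerate(steps, start=1):
        total += s.num_shocks
        lines.append(
            f"{k:<6}{s.power_level:<13}{s.shock_rate:<19}{s.num_shocks:<8}{total:<10}"
        )
    return "\n".join(lines)
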