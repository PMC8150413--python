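"""Synthetic SWL registry: PPC sampling and ramping-protocol simulation.

Real lithotripsy registries are proprietary, so training and evaluation run
on simulated cases that reproduce the structure of expert practice: stepwise
voltage ramping from a low power level, a hold phase at a stone-dependent
maximum power, a session shock budget (3000 shocks for renal stones on the
modeled device), rates from {60, 90, 120, 180}/min chosen from patient
characteristics, and stochastic treatment termination once fragmentation
becomes likely.

Two deliberate features shape the learning problem:

* With ``noise_level = 0`` every emitted step is a deterministic function of
  the patient's PPC and the steps delivered so far; randomness enters only
  through the stopping draw, which decides whether a next step exists at all.
  A sequence model can therefore in principle recover the policy exactly.
* In prolonged treatments the policy escalates power beyond the initial
  maximum (one level per step toward 9) after ``boost_after_holds``
  unsuccessful hold blocks at maximum power.  That decision depends on a
  position count within the sequence — visible to a sequence encoder but not
  recoverable from flattened (averages + last step + PPC) features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .cases import (
    ALLOWED_RATES,
    DEFAULT_LOCATIONS,
    POWER_MAX,
    PPCVector,
    TreatmentPlan,
    ValidationError,
    normalize_plan,
)
from .io import write_cases_csv, write_ppc_csv

# --------------------------------------------------------------------------
# PPC distributions (documented defaults; the source registry publishes none)
# --------------------------------------------------------------------------
#: Parameters of the synthetic PPC population.  Ages and arterial pressures
#: are truncated normals; stone size (mm) is log-normal with median 8 mm,
#: typical of renal stones treated with SWL; binary flags are Bernoulli.
PPC_DISTRIBUTIONS = {
    "gender_p": 0.5,
    "age": {"mean": 52.0, "sd": 14.0, "low": 18.0, "high": 90.0},
    "stone_size": {"log_mean": np.log(8.0), "log_sd": 0.35},
    "map": {"mean": 95.0, "sd": 10.0, "low": 60.0, "high": 140.0},
    "location_p": {loc: p for loc, p in zip(DEFAULT_LOCATIONS, (0.25, 0.20, 0.30, 0.25))},
    "anticoagulant_p": 0.15,
    "sedation_p": 0.5,
    "multiple_stones_p": 0.2,
    "strapping_p": 0.3,
}


def _truncnorm(spec: dict) -> stats.rv_continuous:
    a = (spec["low"] - spec["mean"]) / spec["sd"]
    b = (spec["high"] - spec["mean"]) / spec["sd"]
    return stats.truncnorm(a, b, loc=spec["mean"], scale=spec["sd"])


def ppc_distribution_means() -> dict[str, float]:
    """Exact means of the configured PPC distributions (for calibration checks)."""
    d = PPC_DISTRIBUTIONS
    return {
        "gender": d["gender_p"],
        "age": float(_truncnorm(d["age"]).mean()),
        "stone_size": float(np.exp(d["stone_size"]["log_mean"] + d["stone_size"]["log_sd"] ** 2 / 2)),
        "mean_arterial_pressure": float(_truncnorm(d["map"]).mean()),
        "anticoagulant_use": d["anticoagulant_p"],
        "sedation_use": d["sedation_p"],
        "multiple_stones": d["multiple_stones_p"],
        "strapping": d["strapping_p"],
    }


def sample_ppc(rng: np.random.Generator, n: int) -> list[PPCVector]:
    """Draw ``n`` synthetic preoperative patient characteristic records."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    d = PPC_DISTRIBUTIONS
    age = _truncnorm(d["age"]).rvs(size=n, random_state=rng)
    mapp = _truncnorm(d["map"]).rvs(size=n, random_state=rng)
    size = rng.lognormal(d["stone_size"]["log_mean"], d["stone_size"]["log_sd"], size=n)
    locs = list(d["location_p"])
    loc_idx = rng.choice(len(locs), size=n, p=list(d["location_p"].values()))
    gender = rng.random(n) < d["gender_p"]
    anti = rng.random(n) < d["anticoagulant_p"]
    seda = rng.random(n) < d["sedation_p"]
    multi = rng.random(n) < d["multiple_stones_p"]
    strap = rng.random(n) < d["strapping_p"]
    return [
        PPCVector(
            gender=int(gender[i]), age=float(age[i]), stone_location=locs[loc_idx[i]],
            stone_size=float(size[i]), mean_arterial_pressure=float(mapp[i]),
            anticoagulant_use=int(anti[i]), sedation_use=int(seda[i]),
            multiple_stones=int(multi[i]), strapping=int(strap[i]),
        )
        for i in range(n)
    ]


# --------------------------------------------------------------------------
# Treatment policy
# --------------------------------------------------------------------------
@dataclass
class PolicyParams:
    """Parameters of the expert ramping policy the simulator emulates.

    The plan starts at ``start_power`` and ramps one level per ramp block up
    to a stone-size-dependent maximum.  The per-patient ramp block is
    ``ramp_block + ramp_block_map_coeff * (MAP - 95)`` shocks (rounded to
    tens, clamped to [100, 350]; a zero coefficient keeps ``ramp_block``
    exactly).  The maximum power level is
    ``round(max_power_base + max_power_size_coeff * (size - ref_stone_size)
    + max_power_map_coeff * (MAP - 95))`` clamped to [start_power, 9]:
    larger stones need more energy, and better-perfused patients tolerate
    slightly more.  At maximum power the plan delivers blocks of
    ``hold_block`` shocks, alternating between the PPC-chosen rate and the
    adjacent slower rate when ``alternate_hold_rates`` is set (a pacing
    pattern that also keeps sub-1000-shock hold steps distinct after
    normalization); after each at-max step the treatment ends with
    probability ``stop_hazard_base + stop_hazard_size_coeff *
    (size - ref_stone_size)`` (clamped to [0, 1]; larger stones fragment more
    slowly, hence longer plans).  If the stone has not fragmented after
    ``boost_after_holds`` full blocks at maximum power, power escalates one
    level per step toward 9 — prolonged treatments call for more energy.
    The session never exceeds ``shock_limit`` total shocks.
    """

    start_power: int = 1
    ramp_block: int = 200
    ramp_block_map_coeff: float = 4.0
    max_power_base: int = 7
    max_power_size_coeff: float = 0.25
    max_power_map_coeff: float = 0.03
    ref_stone_size: float = 8.0
    rate_rule: str = "ppc_default"  # or "constant:<rate>"
    stop_hazard_base: float = 0.30
    stop_hazard_size_coeff: float = -0.03
    noise_level: float = 0.0
    shock_limit: int = 3000
    boost_after_holds: int | None = 3
    hold_block: int = 400
    alternate_hold_rates: bool = True
    max_raw_steps: int = 200  # safety guard for degenerate policies

    def __post_init__(self) -> None:
        if not 1 <= self.start_power <= POWER_MAX:
            raise ValidationError("start_power outside 1-9")
        if self.ramp_block < 1:
            raise ValidationError("ramp_block must be >= 1")
        if not 0.0 <= self.noise_level <= 1.0:
            raise ValidationError("noise_level outside [0, 1]")
        if self.shock_limit < 1:
            raise ValidationError("shock_limit must be >= 1")

    def ramp_block_for(self, ppc: PPCVector) -> int:
        """Per-patient ramp block: slower escalation (smaller blocks) at low
        arterial pressure, rounded to tens of shocks, clamped to [100, 350]."""
        raw = self.ramp_block + self.ramp_block_map_coeff * (
            ppc.mean_arterial_pressure - 95.0)
        return int(np.clip(round(raw / 10.0) * 10, 100, 350))

    def max_power_for(self, ppc: PPCVector) -> int:
        raw = round(self.max_power_base
                    + self.max_power_size_coeff * (ppc.stone_size - self.ref_stone_size)
                    + self.max_power_map_coeff * (ppc.mean_arterial_pressure - 95.0))
        return int(np.clip(raw, self.start_power, POWER_MAX))

    def rate_for(self, ppc: PPCVector) -> int:
        if self.rate_rule.startswith("constant:"):
            rate = int(self.rate_rule.split(":", 1)[1])
            if rate not in ALLOWED_RATES:
                raise ValidationError(f"constant rate {rate} not in {ALLOWED_RATES}")
            return rate
        if self.rate_rule != "ppc_default":
            raise ValidationError(f"unknown rate_rule {self.rate_rule!r}")
        # slow rates for fragile patients, fast for small stones in the young
        if ppc.anticoagulant_use:
            return 60
        if ppc.age >= 65:
            return 90
        if ppc.stone_size < 6 and ppc.age < 40:
            return 180
        return 120

    def stop_probability(self, ppc: PPCVector) -> float:
        p = self.stop_hazard_base + self.stop_hazard_size_coeff * (ppc.stone_size - self.ref_stone_size)
        return float(np.clip(p, 0.0, 1.0))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PolicyParams":
        return cls(**d)


def _adjacent_rate(rate: int, rng: np.random.Generator) -> int:
    i = ALLOWED_RATES.index(rate)
    if i == 0:
        return ALLOWED_RATES[1]
    if i == len(ALLOWED_RATES) - 1:
        return ALLOWED_RATES[-2]
    return ALLOWED_RATES[i + rng.choice((-1, 1))]


def simulate_case(
    ppc: PPCVector, policy: PolicyParams, rng: np.random.Generator, case_id: str = "case"
) -> TreatmentPlan:
    """Simulate one expert treatment under the ramping policy.

    Returns the normalized plan (merged blocks re-capped at 1000 shocks).
    """
    rate = policy.rate_for(ppc)
    max_p = policy.max_power_for(ppc)
    stop_p = policy.stop_probability(ppc)
    limit = policy.shock_limit
    # the alternate pacing rate: adjacent slower rate (or 90 when already at 60)
    idx = ALLOWED_RATES.index(rate)
    alt_rate = ALLOWED_RATES[idx - 1] if idx > 0 else ALLOWED_RATES[1]

    raw: list[tuple[int, int, int]] = []
    power = policy.start_power
    total = 0
    hold_index = 0
    ramp_block = policy.ramp_block_for(ppc) if policy.ramp_block_map_coeff else policy.ramp_block
    while total < limit and len(raw) < policy.max_raw_steps:
        at_max = power >= max_p
        block = policy.hold_block if at_max else ramp_block
        count = min(block, limit - total)
        step_rate = rate
        if at_max and policy.alternate_hold_rates and hold_index % 2 == 1:
            step_rate = alt_rate
        if policy.noise_level > 0 and rng.random() < policy.noise_level:
            if rng.random() < 0.5:
                step_rate = _adjacent_rate(step_rate, rng)
            else:
                # power-increment deviation: skip one level on the next ramp step
                power = min(power + 1, max_p)
        raw.append((power, step_rate, count))
        total += count
        if at_max:
            hold_index += 1
            # at (or beyond) maximum power the stone may fragment after any step
            if rng.random() < stop_p:
                break
            if policy.boost_after_holds is not None and hold_index >= policy.boost_after_holds:
                power = min(power + 1, POWER_MAX)
        else:
            power += 1
    return normalize_plan(raw, case_id=case_id)


@dataclass
class SyntheticRegistry:
    """A reproducible collection of simulated (PPC, plan) cases."""

    cases: list[tuple[PPCVector, TreatmentPlan]]
    policy: PolicyParams
    seed: int

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cases_csv(out / "cases.csv",
                        [(plan.case_id, [s.as_tuple() for s in plan.steps])
                         for _, plan in self.cases])
        write_ppc_csv(out / "ppc.csv",
                      [(plan.case_id, ppc) for ppc, plan in self.cases])


def generate_registry(n_cases: int, policy: PolicyParams | None = None, seed: int = 0) -> SyntheticRegistry:
    """Simulate ``n_cases`` independent cases, fully determined by (policy, seed)."""
    if n_cases < 1:
        raise ValidationError(f"n_cases must be >= 1, got {n_cases}")
    policy = policy if policy is not None else PolicyParams()
    rng = np.random.default_rng(seed)
    ppcs = sample_ppc(rng, n_cases)
    width = len(str(n_cases - 1))
    cases = [
        (ppc, simulate_case(ppc, policy, rng, case_id=f"case{idx:0{width}d}"))
        for idx, ppc in enumerate(ppcs)
    ]
    return SyntheticRegistry(cases=cases, policy=policy, seed=seed)
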