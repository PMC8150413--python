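"""Domain types and case-preparation algorithms for SWL treatment plans.

A shock wave lithotripsy (SWL) treatment is an ordered sequence of
shock-delivery steps, each a (power level, shock rate, number of shocks)
ternary, together with the preoperative patient characteristics (PPC)
known before the session.  This module defines those objects, the step
normalization rule (merge contiguous same-setting records, then cap steps
at 1000 shocks), the exhaustive prefix decomposition that turns an n-step
case into n-1 next-step supervision samples, and the leakage-free
case-level train/validation split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

POWER_MIN = 1
POWER_MAX = 9
ALLOWED_RATES = (60, 90, 120, 180)
STEP_SHOCK_CAP = 1000

#: Default vocabulary for the stone-location one-hot block.  The encoding is
#: configurable because location coding schemes differ between registries.
DEFAULT_LOCATIONS = ("upper_calyx", "middle_calyx", "lower_calyx", "renal_pelvis")


class ValidationError(ValueError):
    """Raised when a record violates a treatment-step or PPC invariant."""


@dataclass(frozen=True)
class TreatmentStep:
    """One shock-delivery step: a block of shocks at fixed power and rate."""

    power_level: int
    shock_rate: int
    num_shocks: int

    def __post_init__(self) -> None:
        if not POWER_MIN <= self.power_level <= POWER_MAX:
            raise ValidationError(
                f"power_level {self.power_level} outside [{POWER_MIN}, {POWER_MAX}]"
            )
        if self.shock_rate not in ALLOWED_RATES:
            raise ValidationError(
                f"shock_rate {self.shock_rate} not in {ALLOWED_RATES}"
            )
        if self.num_shocks < 1:
            raise ValidationError(f"num_shocks {self.num_shocks} < 1")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.power_level, self.shock_rate, self.num_shocks)


@dataclass(frozen=True)
class TreatmentPlan:
    """An ordered sequence of treatment steps for one case."""

    case_id: str
    steps: tuple[TreatmentStep, ...]

    def __post_init__(self) -> None:
        if len(self.steps) < 1:
            raise ValidationError(f"plan {self.case_id} has no steps")
        object.__setattr__(self, "steps", tuple(self.steps))

    @property
    def total_shocks(self) -> int:
        return sum(s.num_shocks for s in self.steps)

    @property
    def n_steps(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class PPCVector:
    """Preoperative patient characteristics.

    ``stone_location`` is a categorical label from a configurable vocabulary;
    ``encode`` produces the fixed-width numeric vector (binary fields, scalars
    and the location one-hot block).  An unknown location encodes as an
    all-zero one-hot block.
    """

    gender: int
    age: float
    stone_location: str
    stone_size: float
    mean_arterial_pressure: float
    anticoagulant_use: int
    sedation_use: int
    multiple_stones: int
    strapping: int

    def __post_init__(self) -> None:
        for name in ("gender", "anticoagulant_use", "sedation_use",
                     "multiple_stones", "strapping"):
            if getattr(self, name) not in (0, 1):
                raise ValidationError(f"{name} must be 0/1, got {getattr(self, name)}")
        for name in ("age", "stone_size", "mean_arterial_pressure"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValidationError(f"{name} is not finite: {v}")
        if self.age <= 0:
            raise ValidationError(f"age must be positive, got {self.age}")
        if self.stone_size <= 0:
            raise ValidationError(f"stone_size must be positive, got {self.stone_size}")

    def encode(self, locations: Sequence[str] = DEFAULT_LOCATIONS) -> np.ndarray:
        """Numeric encoding: [gender, age, size, MAP, 4 binary flags, loc one-hot]."""
        loc = np.zeros(len(locations))
        if self.stone_location in locations:
            loc[list(locations).index(self.stone_location)] = 1.0
        head = np.array(
            [
                float(self.gender),
                float(self.age),
                float(self.stone_size),
                float(self.mean_arterial_pressure),
                float(self.anticoagulant_use),
                float(self.sedation_use),
                float(self.multiple_stones),
                float(self.strapping),
            ]
        )
        return np.concatenate([head, loc])


#: Indices of continuous entries in the encoded PPC vector (z-scored at training).
CONTINUOUS_PPC_INDICES = (1, 2, 3)


def ppc_width(locations: Sequence[str] = DEFAULT_LOCATIONS) -> int:
    return 8 + len(locations)


@dataclass(frozen=True)
class StepSample:
    """One next-step supervision unit: (first i steps, PPC) -> step i+1."""

    case_id: str
    prefix: tuple[TreatmentStep, ...]
    ppc: PPCVector
    target: TreatmentStep

    def __post_init__(self) -> None:
        object.__setattr__(self, "prefix", tuple(self.prefix))

    @property
    def prefix_length(self) -> int:
        return len(self.prefix)


@dataclass
class SampleDataset:
    """Step samples with a leakage-free case-level train/validation tagging."""

    samples: list[StepSample]
    split_labels: list[str]  # "train" or "val", parallel to samples

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.split_labels):
            raise ValidationError("samples and split_labels length mismatch")

    @property
    def train_samples(self) -> list[StepSample]:
        return [s for s, lab in zip(self.samples, self.split_labels) if lab == "train"]

    @property
    def val_samples(self) -> list[StepSample]:
        return [s for s, lab in zip(self.samples, self.split_labels) if lab == "val"]


def normalize_plan(
    raw_steps: Iterable[tuple[int, int, int]], case_id: str = "case"
) -> TreatmentPlan:
    """Normalize raw delivery records into canonical treatment steps.

    Steps are identified by a change in power level or shock rate:
    consecutive records with identical (power, rate) are merged.  Any merged
    block with more than 1000 shocks is then split into consecutive steps of
    1000 shocks plus a final remainder (a block of exactly 1000 is left
    alone).  Total shocks and relative order are conserved.
    """
    records = list(raw_steps)
    if not records:
        raise ValidationError(f"plan {case_id}: no delivery records")
    # validate eagerly so the error names the offending record
    for idx, (p, r, n) in enumerate(records):
        if not POWER_MIN <= p <= POWER_MAX:
            raise ValidationError(f"record {idx} of {case_id}: power_level {p} outside 1-9")
        if r not in ALLOWED_RATES:
            raise ValidationError(f"record {idx} of {case_id}: shock_rate {r} not in {ALLOWED_RATES}")
        if n < 1:
            raise ValidationError(f"record {idx} of {case_id}: num_shocks {n} < 1")

    merged: list[list[int]] = []
    for p, r, n in records:
        if merged and merged[-1][0] == p and merged[-1][1] == r:
            merged[-1][2] += n
        else:
            merged.append([p, r, n])

    steps: list[TreatmentStep] = []
    for p, r, n in merged:
        while n > STEP_SHOCK_CAP:
            steps.append(TreatmentStep(p, r, STEP_SHOCK_CAP))
            n -= STEP_SHOCK_CAP
        steps.append(TreatmentStep(p, r, n))
    return TreatmentPlan(case_id=case_id, steps=tuple(steps))


def decompose_case(plan: TreatmentPlan, ppc: PPCVector) -> list[StepSample]:
    """Exhaustively decompose a normalized n-step case into n-1 prefix samples.

    Sample i (1 <= i <= n-1) pairs the first i steps and the PPC with step
    i+1 as the target.  A 1-step plan yields no samples (there is no next
    step to learn) and emits a warning.
    """
    n = plan.n_steps
    if n < 2:
        warnings.warn(
            f"case {plan.case_id}: 1-step plan has no next step to learn; "
            "no samples produced",
            stacklevel=2,
        )
        return []
    return [
        StepSample(
            case_id=plan.case_id,
            prefix=plan.steps[:i],
            ppc=ppc,
            target=plan.steps[i],
        )
        for i in range(1, n)
    ]


def split_dataset(
    samples: Sequence[StepSample],
    validation_fraction: float = 0.10,
    seed: int = 0,
) -> SampleDataset:
    """Tag samples train/val, splitting at the case level.

    All samples sharing a case_id receive the same tag, so no case leaks
    across the split.  Cases are greedily assigned (in seeded shuffled order)
    to validation while doing so brings the validation *sample* fraction
    closer to the requested value; at least one case lands on each side.
    """
    if not 0 < validation_fraction < 1:
        raise ValidationError(f"validation_fraction {validation_fraction} not in (0, 1)")
    case_sizes: dict[str, int] = {}
    for s in samples:
        case_sizes[s.case_id] = case_sizes.get(s.case_id, 0) + 1
    if len(case_sizes) < 2:
        raise ValidationError("need at least 2 distinct cases to split")

    rng = np.random.default_rng(seed)
    case_ids = sorted(case_sizes)
    rng.shuffle(case_ids)

    target = validation_fraction * len(samples)
    val_cases: set[str] = set()
    val_count = 0
    for cid in case_ids:
        size = case_sizes[cid]
        if abs(val_count + size - target) < abs(val_count - target):
            val_cases.add(cid)
            val_count += size
    if not val_cases:  # degenerate target smaller than any case
        val_cases.add(case_ids[0])
    if len(val_cases) == len(case_ids):
        val_cases.discard(case_ids[-1])

    labels = ["val" if s.case_id in val_cases else "train" for s in samples]
    return SampleDataset(samples=list(samples), split_labels=labels)
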