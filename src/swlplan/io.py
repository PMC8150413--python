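"""On-disk formats: delimited tables for cases/PPC, JSON for samples and plans.

``cases.csv`` holds one row per raw delivery record
(case_id, step_index, power_level, shock_rate, num_shocks); ``ppc.csv`` one
row per case with the PPC fields (stone location as a categorical string).
Decomposed samples are serialized as JSON lines; plans as JSON objects.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cases import (
    PPCVector,
    SampleDataset,
    StepSample,
    TreatmentPlan,
    TreatmentStep,
    ValidationError,
    normalize_plan,
)

PPC_COLUMNS = [
    "case_id", "gender", "age", "stone_location", "stone_size",
    "mean_arterial_pressure", "anticoagulant_use", "sedation_use",
    "multiple_stones", "strapping",
]


def write_cases_csv(path: str | Path, cases: Iterable[tuple[str, Sequence[tuple[int, int, int]]]]) -> None:
    rows = []
    for case_id, steps in cases:
        for idx, (p, r, n) in enumerate(steps):
            rows.append({"case_id": case_id, "step_index": idx,
                         "power_level": p, "shock_rate": r, "num_shocks": n})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cases_csv(path: str | Path) -> dict[str, list[tuple[int, int, int]]]:
    """Raw delivery records grouped by case, ordered by step_index."""
    df = pd.read_csv(path)
    required = {"case_id", "step_index", "power_level", "shock_rate", "num_shocks"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"cases table missing columns: {sorted(missing)}")
    out: dict[str, list[tuple[int, int, int]]] = {}
    for cid, grp in df.sort_values(["case_id", "step_index"]).groupby("case_id", sort=True):
        out[str(cid)] = [
            (int(p), int(r), int(n))
            for p, r, n in zip(grp.power_level, grp.shock_rate, grp.num_shocks)
        ]
    return out


def write_ppc_csv(path: str | Path, ppcs: Iterable[tuple[str, PPCVector]]) -> None:
    rows = []
    for case_id, ppc in ppcs:
        rows.append({
            "case_id": case_id, "gender": ppc.gender, "age": ppc.age,
            "stone_location": ppc.stone_location, "stone_size": ppc.stone_size,
            "mean_arterial_pressure": ppc.mean_arterial_pressure,
            "anticoagulant_use": ppc.anticoagulant_use,
            "sedation_use": ppc.sedation_use,
            "multiple_stones": ppc.multiple_stones, "strapping": ppc.strapping,
        })
    pd.DataFrame(rows, columns=PPC_COLUMNS).to_csv(path, index=False)


def read_ppc_csv(path: str | Path) -> dict[str, PPCVector]:
    df = pd.read_csv(path)
    missing = set(PPC_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"ppc table missing columns: {sorted(missing)}")
    out: dict[str, PPCVector] = {}
    for row in df.itertuples(index=False):
        out[str(row.case_id)] = PPCVector(
            gender=int(row.gender), age=float(row.age),
            stone_location=str(row.stone_location), stone_size=float(row.stone_size),
            mean_arterial_pressure=float(row.mean_arterial_pressure),
            anticoagulant_use=int(row.anticoagulant_use),
            sedation_use=int(row.sedation_use),
            multiple_stones=int(row.multiple_stones), strapping=int(row.strapping),
        )
    return out


def load_and_normalize(cases_path: str | Path, ppc_path: str | Path) -> list[tuple[PPCVector, TreatmentPlan]]:
    """Read the two registry tables and return normalized (PPC, plan) pairs."""
    raw = read_cases_csv(cases_path)
    ppcs = read_ppc_csv(ppc_path)
    missing = set(raw) - set(ppcs)
    if missing:
        raise ValidationError(f"cases without PPC rows: {sorted(missing)[:5]}")
    return [(ppcs[cid], normalize_plan(steps, case_id=cid)) for cid, steps in raw.items()]


def _step_to_obj(s: TreatmentStep) -> dict:
    return {"power_level": s.power_level, "shock_rate": s.shock_rate,
            "num_shocks": s.num_shocks}


def _step_from_obj(o: dict) -> TreatmentStep:
    return TreatmentStep(int(o["power_level"]), int(o["shock_rate"]), int(o["num_shocks"]))


def _ppc_to_obj(p: PPCVector) -> dict:
    return {
        "gender": p.gender, "age": p.age, "stone_location": p.stone_location,
        "stone_size": p.stone_size, "mean_arterial_pressure": p.mean_arterial_pressure,
        "anticoagulant_use": p.anticoagulant_use, "sedation_use": p.sedation_use,
        "multiple_stones": p.multiple_stones, "strapping": p.strapping,
    }


def _ppc_from_obj(o: dict) -> PPCVector:
    return PPCVector(
        gender=int(o["gender"]), age=float(o["age"]),
        stone_location=str(o["stone_location"]), stone_size=float(o["stone_size"]),
        mean_arterial_pressure=float(o["mean_arterial_pressure"]),
        anticoagulant_use=int(o["anticoagulant_use"]), sedation_use=int(o["sedation_use"]),
        multiple_stones=int(o["multiple_stones"]), strapping=int(o["strapping"]),
    )


def write_samples_jsonl(path: str | Path, dataset: SampleDataset) -> None:
    with open(path, "w") as fh:
        for sample, label in zip(dataset.samples, dataset.split_labels):
            fh.write(json.dumps({
                "case_id": sample.case_id,
                "prefix": [_step_to_obj(s) for s in sample.prefix],
                "ppc": _ppc_to_obj(sample.ppc),
                "target": _step_to_obj(sample.target),
                "prefix_length": sample.prefix_length,
                "split": label,
            }) + "\n")


def read_samples_jsonl(path: str | Path) -> SampleDataset:
    samples, labels = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            samples.append(StepSample(
                case_id=str(obj["case_id"]),
                prefix=tuple(_step_from_obj(s) for s in obj["prefix"]),
                ppc=_ppc_from_obj(obj["ppc"]),
                target=_step_from_obj(obj["target"]),
            ))
            labels.append(str(obj["split"]))
    return SampleDataset(samples=samples, split_labels=labels)


def plan_to_json(plan: TreatmentPlan) -> str:
    return json.dumps({
        "case_id": plan.case_id,
        "steps": [_step_to_obj(s) for s in plan.steps],
        "total_shocks": plan.total_shocks,
    }, indent=2)


def plan_from_json(text: str) -> TreatmentPlan:
    obj = json.loads(text)
    return TreatmentPlan(case_id=str(obj["case_id"]),
                         steps=tuple(_step_from_obj(s) for s in obj["steps"]))


def ppc_from_json(text: str) -> PPCVector:
    return _ppc_from_obj(json.loads(text))


def ppc_to_json(ppc: PPCVector) -> str:
    return json.dumps(_ppc_to_obj(ppc), indent=2)
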