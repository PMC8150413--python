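"""End-to-end reproducible experiment pipeline.

One configuration object fully determines an experiment: simulate a
synthetic registry, decompose cases into next-step samples with a
leakage-free case-level split, train the sequence model and the flattened
baselines, evaluate everything (including the per-prefix-length breakdown
and paired t-tests against the expert reference), and generate sample plans.
All randomness flows from one master seed split into per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baselines import BaselineBundle, fit_baselines
from .cases import SampleDataset, decompose_case, split_dataset
from .evaluation import breakdown_by_prefix_length, evaluate_predictions
from .generator import GeneratorBundle, TrainConfig, train
from .io import plan_to_json, write_samples_jsonl
from .planner import PlanBudget, generate_plan, render_plan
from .registry import PolicyParams, generate_registry, sample_ppc

logger = logging.getLogger("swlplan")


@dataclass
class ExperimentConfig:
    """One file that fully determines an experiment."""

    n_cases: int = 200
    policy: PolicyParams = field(default_factory=PolicyParams)
    validation_fraction: float = 0.10
    train_config: TrainConfig = field(default_factory=TrainConfig)
    shock_limit: int = 3000
    n_generated_plans: int = 5
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        names = ("registry", "split", "train", "baselines", "plans")
        children = ss.spawn(len(names))
        return {name: int(child.generate_state(1)[0] % (2 ** 31))
                for name, child in zip(names, children)}

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "policy": self.policy.to_dict(),
            "validation_fraction": self.validation_fraction,
            "train_config": self.train_config.to_dict(),
            "shock_limit": self.shock_limit,
            "n_generated_plans": self.n_generated_plans,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "policy" in d:
            d["policy"] = PolicyParams.from_dict(d["policy"])
        if "train_config" in d:
            d["train_config"] = TrainConfig.from_dict(d["train_config"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def build_dataset(config: ExperimentConfig) -> tuple[SampleDataset, list]:
    """Simulate, decompose and split; returns the dataset and the registry cases."""
    seeds = config.stage_seeds()
    registry = generate_registry(config.n_cases, config.policy, seed=seeds["registry"])
    samples = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 1-step plans yield no samples
        for ppc, plan in registry.cases:
            samples.extend(decompose_case(plan, ppc))
    dataset = split_dataset(samples, config.validation_fraction, seed=seeds["split"])
    return dataset, registry.cases


def evaluate_all(
    dataset: SampleDataset,
    bundle: GeneratorBundle,
    baselines: BaselineBundle,
) -> dict:
    """Evaluation report for the deep model and every baseline on validation."""
    val = dataset.val_samples
    deep_preds = [bundle.predict_step(s.prefix, s.ppc) for s in val]
    report: dict = {
        "n_validation": len(val),
        "deep_learning": evaluate_predictions(val, deep_preds),
        "breakdown_by_prefix_length": breakdown_by_prefix_length(val, deep_preds),
        "baselines": {},
    }
    base_preds = baselines.predict(val)
    from .cases import TreatmentStep  # local to avoid cycle noise

    for task in ("power", "rate", "count"):
        for name, values in base_preds[task].items():
            key = f"{name}"
            report["baselines"].setdefault(key, {})
            if task == "power":
                preds = [TreatmentStep(int(v), s.target.shock_rate, s.target.num_shocks)
                         for v, s in zip(values, val)]
                report["baselines"][key]["power"] = evaluate_predictions(val, preds)["power"]
            elif task == "rate":
                preds = [TreatmentStep(s.target.power_level, int(v), s.target.num_shocks)
                         for v, s in zip(values, val)]
                report["baselines"][key]["rate"] = evaluate_predictions(val, preds)["rate"]
            else:
                preds = [TreatmentStep(s.target.power_level, s.target.shock_rate, int(v))
                         for v, s in zip(values, val)]
                report["baselines"][key]["count"] = evaluate_predictions(val, preds)["count"]
    return report


def _tables_from_report(report: dict) -> dict[str, pd.DataFrame]:
    """Render the report as tidy tables (per-task model comparison + breakdown)."""
    rows_power, rows_rate, rows_count = [], [], []
    def cls_row(model, r):
        return {"model": model, "accuracy": r["accuracy"],
                "precision": r["macro_precision"], "recall": r["macro_recall"],
                "f1": r["macro_f1"], "t_statistic": r["t_statistic"],
                "p_value": r["p_value"]}
    rows_power.append(cls_row("deep_learning", report["deep_learning"]["power"]))
    rows_rate.append(cls_row("deep_learning", report["deep_learning"]["rate"]))
    rc = report["deep_learning"]["count"]
    rows_count.append({"model": "deep_learning", "rmse": rc["rmse"], "mae": rc["mae"],
                       "t_statistic": rc["t_statistic"], "p_value": rc["p_value"]})
    for name, tasks in report["baselines"].items():
        if "power" in tasks:
            rows_power.append(cls_row(name, tasks["power"]))
        if "rate" in tasks:
            rows_rate.append(cls_row(name, tasks["rate"]))
        if "count" in tasks:
            c = tasks["count"]
            rows_count.append({"model": name, "rmse": c["rmse"], "mae": c["mae"],
                               "t_statistic": c["t_statistic"], "p_value": c["p_value"]})
    brk = []
    for length, row in report["breakdown_by_prefix_length"].items():
        brk.append({"previous_steps": length, "n": row["n"],
                    "power_accuracy": row["power"]["accuracy"],
                    "power_f1": row["power"]["macro_f1"],
                    "rate_accuracy": row["rate"]["accuracy"],
                    "rate_f1": row["rate"]["macro_f1"],
                    "count_rmse": row["count"]["rmse"],
                    "count_mae": row["count"]["mae"]})
    return {
        "power_generation": pd.DataFrame(rows_power),
        "rate_generation": pd.DataFrame(rows_rate),
        "count_generation": pd.DataFrame(rows_count),
        "breakdown": pd.DataFrame(brk),
    }


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline and write every artifact under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    provenance = {"config": config.to_dict(), "config_hash": config.config_hash(),
                  "seeds": seeds, "version": __version__}

    stage = "simulate"
    try:
        logger.info("stage %s: %d cases", stage, config.n_cases)
        dataset, cases = build_dataset(config)
        from .registry import SyntheticRegistry
        SyntheticRegistry(cases=cases, policy=config.policy,
                          seed=seeds["registry"]).write(out)
        write_samples_jsonl(out / "samples.jsonl", dataset)

        stage = "train"
        tc = TrainConfig.from_dict({**config.train_config.to_dict(),
                                    "seed": seeds["train"]})
        logger.info("stage %s: %d train / %d val samples", stage,
                    len(dataset.train_samples), len(dataset.val_samples))
        bundle = train(dataset, tc)
        bundle.save(out / "model")

        stage = "baselines"
        logger.info("stage %s", stage)
        base = fit_baselines(dataset, seed=seeds["baselines"])
        (out / "baselines_manifest.json").write_text(json.dumps(base.manifest, indent=2))

        stage = "evaluate"
        logger.info("stage %s", stage)
        report = evaluate_all(dataset, bundle, base)
        report["provenance"] = provenance
        (out / "report.json").write_text(json.dumps(report, indent=2))
        for name, df in _tables_from_report(report).items():
            df.to_csv(out / f"table_{name}.csv", index=False)

        stage = "plan"
        logger.info("stage %s: %d plans", stage, config.n_generated_plans)
        rng = np.random.default_rng(seeds["plans"])
        budget = PlanBudget(shock_limit=config.shock_limit)
        plans_dir = out / "plans"
        plans_dir.mkdir(exist_ok=True)
        for k, ppc in enumerate(sample_ppc(rng, config.n_generated_plans)):
            plan = generate_plan(ppc, bundle, budget, case_id=f"generated{k}")
            (plans_dir / f"plan{k}.json").write_text(plan_to_json(plan))
            (plans_dir / f"plan{k}.txt").write_text(render_plan(plan) + "\n")
    except Exception:
        logger.exception("experiment failed at stage %r; partial artifacts kept in %s",
                         stage, out)
        raise
    return report
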