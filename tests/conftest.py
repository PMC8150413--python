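import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from swlplan import (
    ExperimentConfig,
    PPCVector,
    TrainConfig,
    normalize_plan,
    train,
)
from swlplan.baselines import fit_baselines
from swlplan.experiment import build_dataset, evaluate_all

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


TABLE1_RAW = [(i, 120, 100) for i in range(1, 8)] + [(8, 120, 2300)]


@pytest.fixture
def table1_raw():
    """The canonical worked-example ramping plan: 7x100 shocks then 2300 at 8."""
    return list(TABLE1_RAW)


@pytest.fixture
def table1_plan(table1_raw):
    return normalize_plan(table1_raw, case_id="table1")


@pytest.fixture
def some_ppc():
    return PPCVector(
        gender=1, age=55.0, stone_location="renal_pelvis", stone_size=8.0,
        mean_arterial_pressure=95.0, anticoagulant_use=0, sedation_use=1,
        multiple_stones=0, strapping=0,
    )


@pytest.fixture(scope="session")
def study():
    """The main synthetic policy-recovery experiment, trained once per session.

    200 noise-free cases, case-level 90/10 split, default training
    configuration, plus the fitted flattened-feature baselines and the full
    evaluation report.
    """
    config = ExperimentConfig(n_cases=200, seed=1)
    dataset, cases = build_dataset(config)
    bundle = train(dataset, TrainConfig(seed=7))
    baselines = fit_baselines(dataset, seed=11)
    report = evaluate_all(dataset, bundle, baselines)
    return {
        "config": config,
        "dataset": dataset,
        "cases": cases,
        "bundle": bundle,
        "baselines": baselines,
        "report": report,
    }


@pytest.fixture(scope="session")
def tiny_bundle():
    """A quickly trained small model for planner / persistence tests."""
    config = ExperimentConfig(n_cases=30, seed=5)
    dataset, _ = build_dataset(config)
    tc = TrainConfig(hidden_width=8, fc_widths=(16, 8), epochs=30, patience=30,
                     seed=3)
    return train(dataset, tc)
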