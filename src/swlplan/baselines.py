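"""Non-sequential comparison models over flattened prefix features.

Classical models cannot consume a variable-length step sequence, so they see
(1) the average power level, shock rate and shock count over the prefix,
(2) the last step verbatim, and (3) the PPC vector.  Classifiers (logistic
regression, random forest, RBF support vector) predict power level and shock
rate; regressors (linear, random forest, RBF support vector) predict the
shock count.  Predictions are decoded with the same rounding/clamping as the
deep model so the comparison is fair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .cases import (
    ALLOWED_RATES,
    PPCVector,
    SampleDataset,
    StepSample,
    TreatmentStep,
    ValidationError,
)

CLASSIFIER_NAMES = ("logistic_regression", "random_forest", "svm")
REGRESSOR_NAMES = ("linear_regression", "random_forest", "svm")


def flatten_features(prefix: Sequence[TreatmentStep], ppc: PPCVector) -> np.ndarray:
    """[avg power, avg rate, avg count, last power, last rate, last count, PPC...]."""
    if len(prefix) == 0:
        raise ValidationError("flattened features are undefined for an empty prefix")
    powers = np.array([s.power_level for s in prefix], dtype=float)
    rates = np.array([s.shock_rate for s in prefix], dtype=float)
    counts = np.array([s.num_shocks for s in prefix], dtype=float)
    last = prefix[-1]
    head = np.array([
        powers.mean(), rates.mean(), counts.mean(),
        float(last.power_level), float(last.shock_rate), float(last.num_shocks),
    ])
    return np.concatenate([head, ppc.encode()])


def _feature_matrix(samples: Sequence[StepSample]) -> np.ndarray:
    return np.stack([flatten_features(s.prefix, s.ppc) for s in samples])


def _make_classifier(name: str, seed: int):
    if name == "logistic_regression":
        return make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf"))
    raise ValidationError(f"unknown classifier {name!r}")


def _make_regressor(name: str, seed: int):
    if name == "linear_regression":
        return LinearRegression()
    if name == "random_forest":
        return RandomForestRegressor(n_estimators=200, random_state=seed)
    if name == "svm":
        return make_pipeline(StandardScaler(), SVR(kernel="rbf"))
    raise ValidationError(f"unknown regressor {name!r}")


@dataclass
class BaselineBundle:
    """Fitted flattened-feature models plus their configuration manifest."""

    power_models: dict[str, object]
    rate_models: dict[str, object]
    count_models: dict[str, object]
    seed: int
    manifest: dict = field(default_factory=dict)

    def predict(self, samples: Sequence[StepSample]) -> dict[str, dict[str, np.ndarray]]:
        """Per-task, per-model decoded predictions for the given samples."""
        X = _feature_matrix(samples)
        out: dict[str, dict[str, np.ndarray]] = {"power": {}, "rate": {}, "count": {}}
        for name, model in self.power_models.items():
            out["power"][name] = model.predict(X).astype(int)
        for name, model in self.rate_models.items():
            out["rate"][name] = model.predict(X).astype(int)
        for name, model in self.count_models.items():
            raw = np.asarray(model.predict(X), dtype=float)
            out["count"][name] = np.clip(np.round(raw), 1, 1000).astype(int)
        return out


def fit_baselines(dataset: SampleDataset, seed: int = 0) -> BaselineBundle:
    """Fit the six comparison models on the training split.

    A task whose training target has a single class is skipped for the
    classifiers, with a warning — the model would be degenerate.
    """
    train_samples = dataset.train_samples
    if not train_samples:
        raise ValidationError("dataset has an empty training split")
    X = _feature_matrix(train_samples)
    y_power = np.array([s.target.power_level for s in train_samples])
    y_rate = np.array([s.target.shock_rate for s in train_samples])
    y_count = np.array([s.target.num_shocks for s in train_samples], dtype=float)

    power_models: dict[str, object] = {}
    rate_models: dict[str, object] = {}
    count_models: dict[str, object] = {}
    for name in CLASSIFIER_NAMES:
        for task, y, store in (("power", y_power, power_models),
                               ("rate", y_rate, rate_models)):
            if len(np.unique(y)) < 2:
                warnings.warn(
                    f"single-class {task} target: skipping {name} classifier",
                    stacklevel=2,
                )
                continue
            model = _make_classifier(name, seed)
            model.fit(X, y)
            store[name] = model
    for name in REGRESSOR_NAMES:
        model = _make_regressor(name, seed)
        model.fit(X, y_count)
        count_models[name] = model

    manifest = {
        "seed": seed,
        "classifiers": {"logistic_regression": "StandardScaler + LogisticRegression(max_iter=2000)",
                        "random_forest": "RandomForestClassifier(n_estimators=200)",
                        "svm": "StandardScaler + SVC(kernel='rbf')"},
        "regressors": {"linear_regression": "LinearRegression",
                       "random_forest": "RandomForestRegressor(n_estimators=200)",
                       "svm": "StandardScaler + SVR(kernel='rbf')"},
    }
    return BaselineBundle(power_models=power_models, rate_models=rate_models,
                          count_models=count_models, seed=seed, manifest=manifest)
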