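"""Next-step generation model: LSTM prefix encoding + PPC-conditioned heads.

Given the steps delivered so far and the preoperative patient
characteristics, the model emits a probability distribution over the nine
power levels, a distribution over the four shock rates, and a nonnegative
scaled shock count.  Following expert practice reconstruction, the three
tasks are trained as separate networks sharing one architecture template
(a ``shared_trunk`` switch trains a single three-headed network instead).

Step encoding: one-hot power level (9) + one-hot shock rate (4) + shock
count / 1000, giving a width-14 vector per step.  The encoding is exactly
invertible for valid steps.  Continuous PPC fields are z-scored with
statistics fitted on the training split only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .cases import (
    ALLOWED_RATES,
    CONTINUOUS_PPC_INDICES,
    DEFAULT_LOCATIONS,
    POWER_MAX,
    POWER_MIN,
    PPCVector,
    SampleDataset,
    StepSample,
    TreatmentStep,
    ValidationError,
    ppc_width,
)
from .network import (
    Adam,
    Params,
    init_params,
    lstm_forward,
    network_forward,
    network_loss_and_grads,
    softmax,
)

STEP_ENCODING_WIDTH = 9 + 4 + 1
COUNT_SCALE = 1000.0

HEAD_SPECS = {"power": (9, "softmax"), "rate": (4, "softmax"), "count": (1, "relu")}


def encode_step(step: TreatmentStep) -> np.ndarray:
    """Width-14 numeric encoding of one treatment step."""
    v = np.zeros(STEP_ENCODING_WIDTH)
    v[step.power_level - POWER_MIN] = 1.0
    v[9 + ALLOWED_RATES.index(step.shock_rate)] = 1.0
    v[13] = step.num_shocks / COUNT_SCALE
    return v


def decode_step(v: np.ndarray) -> TreatmentStep:
    """Inverse of :func:`encode_step` for valid encodings."""
    if v.shape != (STEP_ENCODING_WIDTH,):
        raise ValidationError(f"step encoding must have width {STEP_ENCODING_WIDTH}")
    power = int(np.argmax(v[:9])) + POWER_MIN
    rate = ALLOWED_RATES[int(np.argmax(v[9:13]))]
    count = int(round(v[13] * COUNT_SCALE))
    return TreatmentStep(power, rate, count)


def encode_prefix(prefix: Sequence[TreatmentStep]) -> np.ndarray:
    """(T, 14) matrix of step encodings; (0, 14) for an empty prefix."""
    if len(prefix) == 0:
        return np.zeros((0, STEP_ENCODING_WIDTH))
    return np.stack([encode_step(s) for s in prefix])


def lstm_encode(prefix: Sequence[TreatmentStep] | np.ndarray, params: Params) -> tuple[np.ndarray, np.ndarray]:
    """Encode a step prefix into the LSTM's final (h, c) state.

    The recurrence starts from the zero state, so an empty prefix returns
    zero vectors.  ``prefix`` may be TreatmentSteps or a pre-encoded (T, 14)
    array.
    """
    X = prefix if isinstance(prefix, np.ndarray) else encode_prefix(prefix)
    T = X.shape[0]
    H = params["lstm_U"].shape[0]
    if T == 0:
        return np.zeros(H), np.zeros(H)
    h, caches = lstm_forward(X[None, :, :], np.array([T]), params)
    # final cell state: reconstruct from the last cache entry
    x_t, h_prev, c_prev, i, f, g, o, tanh_c, m = caches[-1]
    c = f * c_prev + i * g
    return h[0], c[0]


# --------------------------------------------------------------------------
# PPC scaling
# --------------------------------------------------------------------------
@dataclass
class PPCScaler:
    """Z-scores the continuous PPC entries; fitted on the training split."""

    mean: np.ndarray
    std: np.ndarray
    locations: tuple[str, ...] = DEFAULT_LOCATIONS

    @classmethod
    def fit(cls, ppcs: Sequence[PPCVector], locations: Sequence[str] = DEFAULT_LOCATIONS) -> "PPCScaler":
        M = np.stack([p.encode(locations) for p in ppcs])
        idx = list(CONTINUOUS_PPC_INDICES)
        mean = np.zeros(M.shape[1])
        std = np.ones(M.shape[1])
        mean[idx] = M[:, idx].mean(axis=0)
        sd = M[:, idx].std(axis=0)
        std[idx] = np.where(sd > 0, sd, 1.0)
        return cls(mean=mean, std=std, locations=tuple(locations))

    def transform(self, ppc: PPCVector) -> np.ndarray:
        return (ppc.encode(self.locations) - self.mean) / self.std


# --------------------------------------------------------------------------
# Training configuration
# --------------------------------------------------------------------------
@dataclass
class TrainConfig:
    """Hyperparameters of the step-generation networks (all seeded)."""

    hidden_width: int = 64
    fc_widths: tuple[int, int] = (64, 32)
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 600
    patience: int = 100
    seed: int = 0
    shared_trunk: bool = False
    include_first_step: bool = False

    def __post_init__(self) -> None:
        for name in ("hidden_width", "learning_rate", "batch_size", "epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        self.fc_widths = tuple(self.fc_widths)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fc_widths"] = list(self.fc_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "fc_widths" in d:
            d["fc_widths"] = tuple(d["fc_widths"])
        return cls(**d)


# --------------------------------------------------------------------------
# Trained bundle
# --------------------------------------------------------------------------
@dataclass
class GeneratorBundle:
    """Trained step-generation model: per-task parameters plus preprocessing.

    ``nets`` maps task group name to (params, head_kinds).  With separate
    networks the groups are "power", "rate", "count"; with a shared trunk a
    single "shared" group carries all three heads.
    """

    nets: dict[str, tuple[Params, dict[str, str]]]
    scaler: PPCScaler
    config: TrainConfig
    history: dict = field(default_factory=dict)

    def _head_outputs(self, prefix: Sequence[TreatmentStep], ppc: PPCVector) -> dict[str, np.ndarray]:
        X = encode_prefix(prefix)[None, :, :]
        if X.shape[1] == 0:
            X = np.zeros((1, 1, STEP_ENCODING_WIDTH))
        lengths = np.array([len(prefix)])
        P = self.scaler.transform(ppc)[None, :]
        outs: dict[str, np.ndarray] = {}
        for params, head_kinds in self.nets.values():
            o, _ = network_forward(X, lengths, P, params, head_kinds)
            outs.update(o)
        return outs

    def forward(self, prefix: Sequence[TreatmentStep], ppc: PPCVector) -> tuple[np.ndarray, np.ndarray, float]:
        """(power distribution over 9 levels, rate distribution over 4 rates,
        nonnegative predicted scaled count)."""
        outs = self._head_outputs(prefix, ppc)
        return outs["power"][0], outs["rate"][0], float(outs["count"][0, 0])

    def predict_step(self, prefix: Sequence[TreatmentStep], ppc: PPCVector) -> TreatmentStep:
        """Decode the heads into a concrete next step.

        Argmax with lowest-index tie-break (lower power / slower rate); the
        count head's output is rescaled to shocks, rounded and clamped to
        [1, 1000].
        """
        power_dist, rate_dist, count = self.forward(prefix, ppc)
        power = int(np.argmax(power_dist)) + POWER_MIN
        rate = ALLOWED_RATES[int(np.argmax(rate_dist))]
        shocks = int(np.clip(round(count * COUNT_SCALE), 1, 1000))
        return TreatmentStep(power, rate, shocks)

    # -- persistence ------------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        arrays: dict[str, np.ndarray] = {}
        manifest = {
            "config": self.config.to_dict(),
            "locations": list(self.scaler.locations),
            "nets": {},
            "history": self.history,
        }
        for group, (params, head_kinds) in self.nets.items():
            manifest["nets"][group] = {"head_kinds": head_kinds, "params": []}
            for k, v in params.items():
                key = f"{group}__{k}"
                arrays[key] = v
                manifest["nets"][group]["params"].append(k)
        arrays["scaler_mean"] = self.scaler.mean
        arrays["scaler_std"] = self.scaler.std
        np.savez(out / "weights.npz", **arrays)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, model_dir: str | Path) -> "GeneratorBundle":
        model_dir = Path(model_dir)
        manifest = json.loads((model_dir / "manifest.json").read_text())
        data = np.load(model_dir / "weights.npz")
        nets: dict[str, tuple[Params, dict[str, str]]] = {}
        for group, info in manifest["nets"].items():
            params = {k: data[f"{group}__{k}"] for k in info["params"]}
            nets[group] = (params, dict(info["head_kinds"]))
        scaler = PPCScaler(
            mean=data["scaler_mean"], std=data["scaler_std"],
            locations=tuple(manifest["locations"]),
        )
        return cls(nets=nets, scaler=scaler,
                   config=TrainConfig.from_dict(manifest["config"]),
                   history=manifest.get("history", {}))


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------
def _prepare_arrays(
    samples: Sequence[StepSample], scaler: PPCScaler, t_max: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    n = len(samples)
    X = np.zeros((n, max(t_max, 1), STEP_ENCODING_WIDTH))
    lengths = np.zeros(n, dtype=int)
    P = np.zeros((n, scaler.mean.shape[0]))
    y_power = np.zeros(n, dtype=int)
    y_rate = np.zeros(n, dtype=int)
    y_count = np.zeros(n)
    for j, s in enumerate(samples):
        enc = encode_prefix(s.prefix)
        X[j, : enc.shape[0], :] = enc
        lengths[j] = enc.shape[0]
        P[j] = scaler.transform(s.ppc)
        y_power[j] = s.target.power_level - POWER_MIN
        y_rate[j] = ALLOWED_RATES.index(s.target.shock_rate)
        y_count[j] = s.target.num_shocks / COUNT_SCALE
    return X, lengths, P, {"power": y_power, "rate": y_rate, "count": y_count}


def _first_step_samples(samples: Sequence[StepSample]) -> list[StepSample]:
    """Synthesize one empty-prefix sample per case targeting its first step."""
    seen: dict[str, StepSample] = {}
    for s in samples:
        if s.case_id not in seen:
            seen[s.case_id] = StepSample(
                case_id=s.case_id, prefix=(), ppc=s.ppc, target=s.prefix[0]
            )
    return list(seen.values())


def _train_one(
    group: str,
    head_kinds: dict[str, str],
    head_sizes: dict[str, int],
    train_arrays,
    val_arrays,
    config: TrainConfig,
    ppc_dim: int,
    seed: int,
) -> tuple[Params, dict]:
    X, lengths, P, targets = train_arrays
    params = init_params(
        STEP_ENCODING_WIDTH, ppc_dim, config.hidden_width, config.fc_widths,
        head_sizes, seed=seed,
    )
    opt = Adam(lr=config.learning_rate)
    rng = np.random.default_rng(seed + 1)
    n = X.shape[0]
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    bad_epochs = 0
    log: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, _, grads = network_loss_and_grads(
                X[idx], lengths[idx], P[idx], params, head_kinds,
                {k: v[idx] for k, v in targets.items()},
            )
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
        log["train_loss"].append(epoch_loss / n)
        if val_arrays is not None:
            Xv, lv, Pv, tv = val_arrays
            outs, _ = network_forward(Xv, lv, Pv, params, head_kinds)
            val_loss = 0.0
            for name, kind in head_kinds.items():
                if kind == "softmax":
                    probs = outs[name][np.arange(Xv.shape[0]), tv[name]]
                    val_loss += float(-np.mean(np.log(probs + 1e-12)))
                else:
                    val_loss += float(np.mean((outs[name][:, 0] - tv[name]) ** 2))
            log["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                # plateau schedule: halve the learning rate while waiting
                if bad_epochs % max(config.patience // 3, 5) == 0:
                    opt.lr *= 0.5
                if bad_epochs >= config.patience:
                    break
        else:
            best_params = params
    return best_params, log


def train(dataset: SampleDataset, config: TrainConfig | None = None) -> GeneratorBundle:
    """Train the step-generation model on the dataset's training split.

    Classification heads (power level, shock rate) minimize categorical
    cross-entropy; the count head minimizes MSE on the count/1000 scale.
    Early stopping monitors the validation split when one exists; the
    parameters with the best validation loss are kept.  With a fixed seed and
    a single thread the trajectory is reproducible.
    """
    config = config if config is not None else TrainConfig()
    train_samples = dataset.train_samples
    if not train_samples:
        raise ValidationError("dataset has an empty training split")
    if config.include_first_step:
        train_samples = train_samples + _first_step_samples(train_samples)
    val_samples = dataset.val_samples

    scaler = PPCScaler.fit([s.ppc for s in train_samples])
    t_max = max(
        [s.prefix_length for s in train_samples]
        + [s.prefix_length for s in val_samples] + [1]
    )
    train_arrays = _prepare_arrays(train_samples, scaler, t_max)
    val_arrays = _prepare_arrays(val_samples, scaler, t_max) if val_samples else None
    ppc_dim = scaler.mean.shape[0]

    nets: dict[str, tuple[Params, dict[str, str]]] = {}
    history: dict[str, dict] = {}
    if config.shared_trunk:
        head_kinds = {name: kind for name, (_, kind) in HEAD_SPECS.items()}
        head_sizes = {name: size for name, (size, _) in HEAD_SPECS.items()}
        params, log = _train_one("shared", head_kinds, head_sizes, train_arrays,
                                 val_arrays, config, ppc_dim, config.seed)
        nets["shared"] = (params, head_kinds)
        history["shared"] = log
    else:
        for offset, (name, (size, kind)) in enumerate(HEAD_SPECS.items()):
            params, log = _train_one(
                name, {name: kind}, {name: size}, train_arrays, val_arrays,
                config, ppc_dim, config.seed + 101 * offset,
            )
            nets[name] = (params, {name: kind})
            history[name] = log
    return GeneratorBundle(nets=nets, scaler=scaler, config=config, history=history)
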