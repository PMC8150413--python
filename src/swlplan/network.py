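"""Compact numpy implementation of the sequence network and its training.

The architecture: an LSTM encodes the variable-length prefix of treatment
steps into its final hidden state; that state is concatenated with the PPC
vector and passed through two fully connected ReLU layers; a task head maps
the result to either a softmax distribution over classes (power level, shock
rate) trained with categorical cross-entropy, or a ReLU scalar (scaled shock
count) trained with mean squared error.  Optimization is Adam.

Everything is plain numpy with explicit backpropagation: the model is small
(hidden width ~32, a few thousand samples) and exact control over the
recurrence, initialization and determinism matters more than speed here.

LSTM recurrence (gate order i, f, g, o; zero initial state):

    z = x_t W + h_{t-1} U + b
    i = sigma(z_i),  f = sigma(z_f),  g = tanh(z_g),  o = sigma(z_o)
    c_t = f * c_{t-1} + i * g
    h_t = o * tanh(c_t)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

Params = dict[str, np.ndarray]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def init_params(
    input_dim: int,
    ppc_dim: int,
    hidden: int,
    fc_widths: tuple[int, int],
    heads: Mapping[str, int],
    seed: int,
) -> Params:
    """Glorot-uniform weights, zero biases, for the LSTM + trunk + heads."""
    rng = np.random.default_rng(seed)
    f1, f2 = fc_widths
    p: Params = {
        "lstm_W": _glorot(rng, (input_dim, 4 * hidden)),
        "lstm_U": _glorot(rng, (hidden, 4 * hidden)),
        "lstm_b": np.zeros(4 * hidden),
        "fc1_W": _glorot(rng, (hidden + ppc_dim, f1)),
        "fc1_b": np.zeros(f1),
        "fc2_W": _glorot(rng, (f1, f2)),
        "fc2_b": np.zeros(f2),
    }
    for name, size in heads.items():
        p[f"head_{name}_W"] = _glorot(rng, (f2, size))
        p[f"head_{name}_b"] = np.zeros(size)
    return p


def zero_like(params: Params) -> Params:
    return {k: np.zeros_like(v) for k, v in params.items()}


# --------------------------------------------------------------------------
# LSTM forward / backward over a padded batch
# --------------------------------------------------------------------------
def lstm_forward(
    X: np.ndarray, lengths: np.ndarray, params: Params
) -> tuple[np.ndarray, list]:
    """Run the recurrence over a zero-padded batch.

    X: (B, T, D); lengths: (B,) number of valid timesteps per row.  For rows
    already past their length the state is carried through unchanged, so the
    returned h (B, H) is each row's state after its final valid step; rows
    with length 0 return the zero initial state.
    """
    W, U, b = params["lstm_W"], params["lstm_U"], params["lstm_b"]
    B, T, _ = X.shape
    H = U.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    caches = []
    for t in range(T):
        x_t = X[:, t, :]
        z = x_t @ W + h @ U + b
        i = sigmoid(z[:, :H])
        f = sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        m = (t < lengths).astype(float)[:, None]
        caches.append((x_t, h, c, i, f, g, o, tanh_c, m))
        c = m * c_new + (1.0 - m) * c
        h = m * h_new + (1.0 - m) * h
    return h, caches


def lstm_backward(dh_final: np.ndarray, caches: list, params: Params) -> Params:
    """Backpropagate through time; returns gradients for W, U, b."""
    W, U = params["lstm_W"], params["lstm_U"]
    dW = np.zeros_like(W)
    dU = np.zeros_like(U)
    db = np.zeros_like(params["lstm_b"])
    H = U.shape[0]
    dh = dh_final.copy()
    dc = np.zeros_like(dh)
    for x_t, h_prev, c_prev, i, f, g, o, tanh_c, m in reversed(caches):
        dh_new = m * dh
        dh_prev = (1.0 - m) * dh
        dc_new = m * dc
        dc_prev_carry = (1.0 - m) * dc
        # h_new = o * tanh(c_new)
        do = dh_new * tanh_c
        dc_new = dc_new + dh_new * o * (1.0 - tanh_c ** 2)
        # c_new = f * c_prev + i * g
        df = dc_new * c_prev
        dc_prev = dc_new * f
        di = dc_new * g
        dg = dc_new * i
        dz = np.concatenate(
            [di * i * (1.0 - i), df * f * (1.0 - f),
             dg * (1.0 - g ** 2), do * o * (1.0 - o)],
            axis=1,
        )
        dW += x_t.T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh = dh_prev + dz @ U.T
        dc = dc_prev_carry + dc_prev
    return {"lstm_W": dW, "lstm_U": dU, "lstm_b": db}


# --------------------------------------------------------------------------
# Full network
# --------------------------------------------------------------------------
def network_forward(
    X: np.ndarray,
    lengths: np.ndarray,
    P: np.ndarray,
    params: Params,
    head_kinds: Mapping[str, str],
) -> tuple[dict[str, np.ndarray], dict]:
    """Forward pass.  head_kinds maps head name -> 'softmax' | 'relu'.

    Returns per-head outputs (probabilities for softmax heads, nonnegative
    activations for relu heads) and a cache for backprop.
    """
    h, lstm_cache = lstm_forward(X, lengths, params)
    u = np.concatenate([h, P], axis=1)
    z1 = u @ params["fc1_W"] + params["fc1_b"]
    a1 = np.maximum(z1, 0.0)
    z2 = a1 @ params["fc2_W"] + params["fc2_b"]
    a2 = np.maximum(z2, 0.0)
    outputs: dict[str, np.ndarray] = {}
    head_pre: dict[str, np.ndarray] = {}
    for name, kind in head_kinds.items():
        logits = a2 @ params[f"head_{name}_W"] + params[f"head_{name}_b"]
        head_pre[name] = logits
        if kind == "softmax":
            outputs[name] = softmax(logits)
        elif kind == "relu":
            outputs[name] = np.maximum(logits, 0.0)
        else:
            raise ValueError(f"unknown head kind {kind!r}")
    if not all(np.all(np.isfinite(v)) for v in outputs.values()):
        raise FloatingPointError("non-finite activations in network forward pass")
    cache = {"lstm": lstm_cache, "u": u, "z1": z1, "a1": a1, "z2": z2, "a2": a2,
             "head_pre": head_pre, "P_dim": P.shape[1]}
    return outputs, cache


def network_loss_and_grads(
    X: np.ndarray,
    lengths: np.ndarray,
    P: np.ndarray,
    params: Params,
    head_kinds: Mapping[str, str],
    targets: Mapping[str, np.ndarray],
) -> tuple[float, dict[str, float], Params]:
    """Total loss (sum over heads of per-sample-mean losses) and gradients.

    Softmax heads use categorical cross-entropy against integer class
    targets; relu heads use mean squared error against float targets.
    """
    outputs, cache = network_forward(X, lengths, P, params, head_kinds)
    B = X.shape[0]
    grads = zero_like(params)
    da2 = np.zeros_like(cache["a2"])
    total = 0.0
    per_head: dict[str, float] = {}
    for name, kind in head_kinds.items():
        out = outputs[name]
        y = targets[name]
        if kind == "softmax":
            eps = 1e-12
            loss = -np.mean(np.log(out[np.arange(B), y] + eps))
            dlogits = out.copy()
            dlogits[np.arange(B), y] -= 1.0
            dlogits /= B
        else:
            pred = out[:, 0]
            diff = pred - y
            loss = float(np.mean(diff ** 2))
            dpred = 2.0 * diff / B
            dlogits = (dpred * (cache["head_pre"][name][:, 0] > 0))[:, None]
        per_head[name] = float(loss)
        total += float(loss)
        grads[f"head_{name}_W"] = cache["a2"].T @ dlogits
        grads[f"head_{name}_b"] = dlogits.sum(axis=0)
        da2 += dlogits @ params[f"head_{name}_W"].T

    dz2 = da2 * (cache["z2"] > 0)
    grads["fc2_W"] = cache["a1"].T @ dz2
    grads["fc2_b"] = dz2.sum(axis=0)
    da1 = dz2 @ params["fc2_W"].T
    dz1 = da1 * (cache["z1"] > 0)
    grads["fc1_W"] = cache["u"].T @ dz1
    grads["fc1_b"] = dz1.sum(axis=0)
    du = dz1 @ params["fc1_W"].T
    H = params["lstm_U"].shape[0]
    dh = du[:, :H]
    grads.update(lstm_backward(dh, cache["lstm"], params))
    return total, per_head, grads


# --------------------------------------------------------------------------
# Adam
# --------------------------------------------------------------------------
@dataclass
class Adam:
    """Standard Adam with bias correction."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: Params = field(default_factory=dict)
    v: Params = field(default_factory=dict)

    def step(self, params: Params, grads: Params) -> None:
        if not self.m:
            self.m = zero_like(params)
            self.v = zero_like(params)
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
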