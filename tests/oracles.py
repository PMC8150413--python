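"""Independent brute-force reference implementations used only by tests.

Each oracle computes the same quantity as the library by a deliberately
different route (shock-by-shock expansion, per-class loops, explicit gate
recurrence) so agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def resegment_shock_by_shock(raw_steps, cap=1000):
    """Normalization oracle: expand to individual shocks, then re-segment.

    A new step starts when (power, rate) changes or the current step reaches
    ``cap`` shocks.
    """
    shocks = []
    for p, r, n in raw_steps:
        shocks.extend([(p, r)] * n)
    steps = []
    for pr in shocks:
        if steps and steps[-1][0] == pr and steps[-1][1] < cap:
            steps[-1][1] += 1
        else:
            steps.append([pr, 1])
    return [(p, r, n) for (p, r), n in steps]


def per_class_metrics(C):
    """Macro metrics by explicit per-class loops (zero denominators -> 0)."""
    C = np.asarray(C, dtype=float)
    k = C.shape[0]
    precisions, recalls, f1s = [], [], []
    for j in range(k):
        col = sum(C[i][j] for i in range(k))
        row = sum(C[j][i] for i in range(k))
        p = C[j][j] / col if col > 0 else 0.0
        r = C[j][j] / row if row > 0 else 0.0
        precisions.append(p)
        recalls.append(r)
        f1s.append(2 * p * r / (p + r) if p + r > 0 else 0.0)
    acc = sum(C[j][j] for j in range(k)) / C.sum()
    return (acc, sum(precisions) / k, sum(recalls) / k, sum(f1s) / k)


def paired_t_closed_form(diffs):
    """t = mean(d) / (sd(d)/sqrt(n)) with the sample (ddof=1) deviation."""
    d = list(diffs)
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    return mean / math.sqrt(var / n)


def lstm_reference(X, W, U, b):
    """Single-sequence LSTM oracle: explicit elementwise gate recurrence."""
    H = U.shape[0]
    h = np.zeros(H)
    c = np.zeros(H)

    def sig(x):
        return 1.0 / (1.0 + np.exp(-x))

    for t in range(X.shape[0]):
        z = X[t] @ W + h @ U + b
        i, f, g, o = z[:H], z[H:2 * H], z[2 * H:3 * H], z[3 * H:]
        i, f, g, o = sig(i), sig(f), np.tanh(g), sig(o)
        c = f * c + i * g
        h = o * np.tanh(c)
    return h, c
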