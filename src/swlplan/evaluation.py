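"""Evaluation statistics: macro-averaged multiclass metrics, count errors,
paired t-tests against expert practice, and the per-prefix-length breakdown.

Conventions: per-class precision/recall with a zero denominator are defined
as 0 and the affected classes are flagged in the report; the macro F1 is the
unweighted mean of per-class F1 scores (not the harmonic mean of macro
precision and macro recall — the two differ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .cases import ALLOWED_RATES, StepSample, ValidationError


@dataclass
class ConfusionMatrix:
    """Counts C[i, j]: samples labeled class i, generated as class j."""

    counts: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValidationError("confusion matrix counts must be nonnegative")
        if len(self.classes) != self.counts.shape[0]:
            raise ValidationError("class labels must match matrix size")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_predictions(cls, true: Sequence, pred: Sequence, classes: Sequence) -> "ConfusionMatrix":
        classes = tuple(classes)
        index = {c: k for k, c in enumerate(classes)}
        C = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(true, pred, strict=True):
            C[index[t], index[p]] += 1
        return cls(counts=C, classes=classes)


def accuracy(cm: ConfusionMatrix) -> float:
    """Proportion of correctly generated observations: trace / total."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def macro_metrics(cm: ConfusionMatrix) -> tuple[float, float, float, list]:
    """(macro precision, macro recall, macro F1, flagged zero-denominator classes).

    Per class k: precision = C[k,k] / column-k sum, recall = C[k,k] / row-k
    sum; macro values are unweighted class means; macro F1 is the mean of
    per-class F1 scores.  Classes with a zero denominator contribute 0.
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    C = cm.counts.astype(float)
    diag = np.diag(C)
    col = C.sum(axis=0)
    row = C.sum(axis=1)
    precision = np.divide(diag, col, out=np.zeros_like(diag), where=col > 0)
    recall = np.divide(diag, row, out=np.zeros_like(diag), where=row > 0)
    pr_sum = precision + recall
    f1 = np.divide(2 * precision * recall, pr_sum,
                   out=np.zeros_like(diag), where=pr_sum > 0)
    flagged = [cm.classes[k] for k in range(len(cm.classes))
               if col[k] == 0 or row[k] == 0]
    return float(precision.mean()), float(recall.mean()), float(f1.mean()), flagged


def rmse_mae(predicted: Sequence[float], true: Sequence[float]) -> tuple[float, float]:
    """Root mean squared error and mean absolute error on the shock scale."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValidationError("predicted/true must be equal-length and nonempty")
    diff = p - t
    return float(np.sqrt(np.mean(diff ** 2))), float(np.mean(np.abs(diff)))


def paired_t(generated: Sequence[float], reference: Sequence[float]) -> tuple[float, float]:
    """Classical paired t-test on generated - reference differences.

    Two-sided p-value.  Conventions for degenerate cases: all-zero
    differences give (t=0, p=1); zero variance with a nonzero mean gives
    (t=+/-inf, p=0).
    """
    g = np.asarray(generated, dtype=float)
    r = np.asarray(reference, dtype=float)
    if g.shape != r.shape or g.size < 2:
        raise ValidationError("paired_t needs equal-length vectors of size >= 2")
    d = g - r
    n = d.size
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


# --------------------------------------------------------------------------
# Report assembly
# --------------------------------------------------------------------------
POWER_CLASSES = tuple(range(1, 10))
RATE_CLASSES = ALLOWED_RATES


def classification_report(true: Sequence, pred: Sequence, classes: Sequence) -> dict:
    cm = ConfusionMatrix.from_predictions(true, pred, classes)
    prec, rec, f1, flagged = macro_metrics(cm)
    if cm.total >= 2:
        t, p = paired_t([float(x) for x in pred], [float(x) for x in true])
    else:  # a single observation carries no paired-difference variance
        t, p = float("nan"), float("nan")
    return {
        "n": cm.total,
        "accuracy": accuracy(cm),
        "macro_precision": prec,
        "macro_recall": rec,
        "macro_f1": f1,
        "zero_denominator_classes": list(flagged),
        "t_statistic": t,
        "p_value": p,
    }


def regression_report(pred: Sequence[float], true: Sequence[float]) -> dict:
    rmse, mae = rmse_mae(pred, true)
    if len(list(true)) >= 2:
        t, p = paired_t(pred, true)
    else:
        t, p = float("nan"), float("nan")
    return {"n": len(list(true)), "rmse": rmse, "mae": mae,
            "t_statistic": t, "p_value": p}


def evaluate_predictions(
    samples: Sequence[StepSample],
    predictions: Sequence,  # TreatmentStep per sample
) -> dict:
    """Full report for one model's decoded predictions on a sample set."""
    true_power = [s.target.power_level for s in samples]
    true_rate = [s.target.shock_rate for s in samples]
    true_count = [s.target.num_shocks for s in samples]
    pred_power = [p.power_level for p in predictions]
    pred_rate = [p.shock_rate for p in predictions]
    pred_count = [p.num_shocks for p in predictions]
    return {
        "power": classification_report(true_power, pred_power, POWER_CLASSES),
        "rate": classification_report(true_rate, pred_rate, RATE_CLASSES),
        "count": regression_report(pred_count, true_count),
    }


def breakdown_by_prefix_length(
    samples: Sequence[StepSample],
    predictions: Sequence,
) -> dict[int, dict]:
    """Per-prefix-length stratified reports (strata with no samples omitted)."""
    strata: dict[int, list[int]] = {}
    for idx, s in enumerate(samples):
        strata.setdefault(s.prefix_length, []).append(idx)
    out: dict[int, dict] = {}
    for length in sorted(strata):
        idx = strata[length]
        sub_samples = [samples[i] for i in idx]
        sub_preds = [predictions[i] for i in idx]
        report = evaluate_predictions(sub_samples, sub_preds)
        # paired t is unstable on tiny strata; keep the metric columns
        out[length] = {
            "n": len(idx),
            "power": {k: report["power"][k] for k in
                      ("accuracy", "macro_precision", "macro_recall", "macro_f1")},
            "rate": {k: report["rate"][k] for k in
                     ("accuracy", "macro_precision", "macro_recall", "macro_f1")},
            "count": {k: report["count"][k] for k in ("rmse", "mae")},
        }
    return out
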