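"""Evaluation metrics from micro-aggregated confusion counts and probabilities.

Multi-class results are reduced to a single TP/TN/FP/FN quadruple by summing
one-vs-rest counts over all K classes ("micro" aggregation); every rate metric
is then computed from the summed counts with its standard textbook definition.
Under single-label micro aggregation ``TP + FN = n`` and accuracy coincides
with micro recall.

Probability-based losses (crossentropy, KL divergence, the hinge family,
Poisson, log-cosh, MAE/MSE/MSLE/RMSE, cosine similarity) are means over
samples of the usual elementwise definitions applied to softmax outputs
against one-hot targets.

Metrics whose denominator is zero are reported as NaN (undefined), never as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "aggregate_confusion",
    "derive_rate_metrics",
    "probability_losses",
    "auc_ovr_macro",
    "full_report",
    "consistency_report",
    "write_report",
]

_EPS = 1e-12

#: rate metrics in presentation order
RATE_METRICS = (
    "Accuracy", "F1", "Precision", "Recall (Sensitivity)", "Specificity",
    "IoU", "Dice", "Youden Index", "NPV", "MCC", "FBeta", "FNR", "FDR",
    "Fallout",
)

LOSS_METRICS = (
    "Categorical Crossentropy", "KLD", "Categorical Hinge", "Hinge",
    "Squared Hinge", "Poisson", "Logcosh Error", "MAE", "MSE", "MSLE",
    "RMSE", "Cosine Similarity",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN summed over all classes."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        """Number of evaluated samples (single-label aggregation)."""
        return self.TP + self.FN

    def to_dict(self) -> dict[str, int]:
        return {"TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN}


def aggregate_confusion(true_labels, predicted_labels, K: int) -> ConfusionCounts:
    """Micro-aggregate one-vs-rest confusion counts over K classes.

    For each class c the sample contributes TP (true c predicted c), FN
    (true c predicted other), FP (other predicted c) or TN; the per-class
    counts are summed.  ``TP + FN = n`` and the four counts total ``n * K``.
    """
    t = np.asarray(true_labels, dtype=int).ravel()
    p = np.asarray(predicted_labels, dtype=int).ravel()
    if t.size != p.size:
        raise ValueError("label vectors differ in length")
    if t.size and (min(t.min(), p.min()) < 0 or max(t.max(), p.max()) >= K):
        raise ValueError(f"labels outside [0, {K - 1}]")
    cm = np.zeros((K, K), dtype=int)
    np.add.at(cm, (t, p), 1)
    diag = np.diag(cm)
    tp = int(diag.sum())
    fp = int((cm.sum(axis=0) - diag).sum())
    fn = int((cm.sum(axis=1) - diag).sum())
    tn = int(t.size * K - tp - fp - fn)
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def derive_rate_metrics(counts: ConfusionCounts, beta: float = 2.0) -> dict[str, float]:
    """All confusion-count rate metrics, as fractions in [0, 1] (NaN if undefined)."""
    TP, TN, FP, FN = counts.TP, counts.TN, counts.FP, counts.FN
    precision = _ratio(TP, TP + FP)
    recall = _ratio(TP, TP + FN)
    specificity = _ratio(TN, TN + FP)
    npv = _ratio(TN, TN + FN)
    mcc_den = math.sqrt(
        float(TP + FP) * float(TP + FN) * float(TN + FP) * float(TN + FN)
    )
    mcc = (TP * TN - FP * FN) / mcc_den if mcc_den > 0 else float("nan")
    f1 = _ratio(2 * precision * recall, precision + recall)
    b2 = beta * beta
    fbeta = _ratio((1 + b2) * precision * recall, b2 * precision + recall)
    return {
        "Accuracy": recall,  # micro accuracy equals TP / (TP + FN)
        "F1": f1,
        "Precision": precision,
        "Recall (Sensitivity)": recall,
        "Specificity": specificity,
        "IoU": _ratio(TP, TP + FP + FN),
        "Dice": _ratio(2 * TP, 2 * TP + FP + FN),
        "Youden Index": recall + specificity - 1.0,
        "NPV": npv,
        "MCC": mcc,
        "FBeta": fbeta,
        "FNR": 1.0 - recall,
        "FDR": 1.0 - precision,
        "Fallout": 1.0 - specificity,
    }


def _check_probs(true_onehot, predicted_probs) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(true_onehot, dtype=float)
    p = np.asarray(predicted_probs, dtype=float)
    if y.shape != p.shape or y.ndim != 2:
        raise ValueError("true_onehot and predicted_probs must share an (n, K) shape")
    if not np.all(np.isfinite(p)):
        raise ValueError("predicted probabilities contain non-finite values")
    if np.any(p.sum(axis=1) <= 0):
        raise ValueError("a probability row sums to zero")
    rows = y.sum(axis=1)
    if not (np.allclose(rows, 1.0) and np.all((y == 0) | (y == 1))):
        raise ValueError("true_onehot is not valid one-hot")
    return y, p


def probability_losses(true_onehot, predicted_probs) -> dict[str, float]:
    """The probability-based loss suite, each a mean over samples."""
    y, p = _check_probs(true_onehot, predicted_probs)
    pc = np.clip(p, _EPS, 1.0)
    yt = 2.0 * y - 1.0  # {-1, +1} encoding for the hinge family
    pos = (y * p).sum(axis=1)
    neg = np.where(y == 1, -np.inf, p).max(axis=1)
    err = p - y
    cos = (y * p).sum(axis=1) / (
        np.linalg.norm(y, axis=1) * np.maximum(np.linalg.norm(p, axis=1), _EPS)
    )
    return {
        "Categorical Crossentropy": float(-(y * np.log(pc)).sum(axis=1).mean()),
        "KLD": float(
            (np.where(y > 0, y * np.log(np.clip(y, _EPS, 1) / pc), 0.0)).sum(axis=1).mean()
        ),
        "Categorical Hinge": float(np.maximum(0.0, 1.0 - pos + neg).mean()),
        "Hinge": float(np.maximum(0.0, 1.0 - yt * p).mean()),
        "Squared Hinge": float((np.maximum(0.0, 1.0 - yt * p) ** 2).mean()),
        "Poisson": float((p - y * np.log(pc)).mean()),
        "Logcosh Error": float(np.log(np.cosh(err)).mean()),
        "MAE": float(np.abs(err).mean()),
        "MSE": float((err ** 2).mean()),
        "MSLE": float(((np.log1p(y) - np.log1p(np.maximum(p, 0))) ** 2).mean()),
        "RMSE": float(np.sqrt((err ** 2).mean())),
        "Cosine Similarity": float(cos.mean()),
    }


def auc_ovr_macro(true_labels, predicted_probs, K: int) -> float:
    """One-vs-rest macro-averaged ROC AUC by trapezoidal integration."""
    t = np.asarray(true_labels, dtype=int).ravel()
    p = np.asarray(predicted_probs, dtype=float)
    present = np.unique(t)
    if present.size < 2:
        return float("nan")
    if present.size < K:
        # restrict to classes present so the one-vs-rest average is defined
        p = p[:, present]
        p = p / np.maximum(p.sum(axis=1, keepdims=True), _EPS)
        t = np.searchsorted(present, t)
    return float(roc_auc_score(t, p if p.shape[1] > 2 else p[:, 1], multi_class="ovr", average="macro"))


def full_report(
    true_labels, predicted_probs, K: int, beta: float = 2.0
) -> tuple[dict[str, float], ConfusionCounts]:
    """Complete metric report from labels and predicted probability rows."""
    t = np.asarray(true_labels, dtype=int).ravel()
    p = np.asarray(predicted_probs, dtype=float)
    pred = p.argmax(axis=1)
    counts = aggregate_confusion(t, pred, K)
    report = derive_rate_metrics(counts, beta=beta)
    onehot = np.eye(K)[t]
    report.update(probability_losses(onehot, p))
    report["AUC"] = auc_ovr_macro(t, p, K)
    return report, counts


def consistency_report(
    counts: ConfusionCounts, printed: dict[str, float], beta: float = 2.0
) -> pd.DataFrame:
    """Compare recomputed rate metrics against externally reported values.

    ``printed`` maps metric names to reported values on their native scale
    (percent for the percent-style rows, plain fractions otherwise); each row
    of the result carries the recomputed value rounded to the reported number
    of decimals and a consistency flag, so discrepant cells can be listed
    instead of asserted.
    """
    recomputed = derive_rate_metrics(counts, beta=beta)
    rows = []
    for name, reported in printed.items():
        if name not in recomputed:
            continue
        value = recomputed[name]
        text = f"{reported}"
        decimals = len(text.split(".")[1]) if "." in text else 0
        scale = 100.0 if name not in ("FNR", "FDR", "Fallout") else 1.0
        rounded = round(value * scale, decimals)
        rows.append(
            {
                "metric": name,
                "recomputed": value * scale,
                "rounded": rounded,
                "reported": reported,
                "consistent": bool(abs(rounded - reported) < 10 ** (-decimals) / 2 + 1e-12),
            }
        )
    return pd.DataFrame(rows)


def write_report(report: dict[str, float], json_path=None, csv_path=None) -> None:
    """Serialize a metric report as JSON and/or a two-column CSV."""
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in report.items()}, fh, indent=2)
    if csv_path is not None:
        pd.DataFrame(
            {"metric": list(report.keys()), "value": list(report.values())}
        ).to_csv(csv_path, index=False)
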