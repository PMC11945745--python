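"""Evaluation: confusion-matrix metrics, ROC/AUC, paired tests, sweeps.

Per-label metrics follow the usual confusion-matrix definitions

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 · precision · recall / (precision + recall)

with zero denominators reported as 0 and flagged degenerate.  In the
multi-label setting "accuracy" is the per-label accuracy averaged over
the five subtypes (subset accuracy is also reported).  ROC curves are
built by grouping tied scores into a single step and integrating with
the trapezoidal rule, which makes the AUC exactly the Mann–Whitney
rank statistic; *micro* AUC pools all (sample, label) pairs across the
five subtypes, *macro* averages per-label AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .network import ModelConfig, forward, predict_labels

__all__ = [
    "ConfusionCounts", "EvaluationError", "confusion", "basic_metrics",
    "roc_curve", "roc_auc", "micro_roc_auc", "macro_auc",
    "evaluate_probabilities", "paired_comparison", "sweep",
    "permutation_importance",
]


class EvaluationError(ValueError):
    """Shape mismatches or degenerate evaluation inputs."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-label TP/FP/TN/FN counts (arrays of length n_labels)."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def n(self) -> np.ndarray:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predicted: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Element-wise per-label confusion counts."""
    predicted = np.atleast_2d(np.asarray(predicted, dtype=int))
    truth = np.atleast_2d(np.asarray(truth, dtype=int))
    if predicted.shape != truth.shape:
        raise EvaluationError("predicted and truth shapes differ")
    for arr, name in ((predicted, "predicted"), (truth, "truth")):
        if not np.isin(arr, (0, 1)).all():
            raise EvaluationError(f"{name} matrix must be binary")
    tp = ((predicted == 1) & (truth == 1)).sum(axis=0)
    fp = ((predicted == 1) & (truth == 0)).sum(axis=0)
    tn = ((predicted == 0) & (truth == 0)).sum(axis=0)
    fn = ((predicted == 0) & (truth == 1)).sum(axis=0)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: np.ndarray, den: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """num/den with 0 (and a degeneracy flag) where den == 0."""
    den = np.asarray(den, dtype=float)
    flagged = den == 0
    out = np.divide(num, den, out=np.zeros_like(den, dtype=float),
                    where=~flagged)
    return out, flagged


def basic_metrics(counts: ConfusionCounts) -> pd.DataFrame:
    """Accuracy/precision/recall/F1 per label plus a macro row.

    Zero-denominator cases (e.g. no positive predictions) yield 0 with
    ``degenerate=True`` — the convention under which a never-positive
    classifier on a rare label scores recall 0, not NaN.
    """
    if (counts.n < 1).any():
        raise EvaluationError("empty confusion counts")
    tp, fp, tn, fn = (a.astype(float) for a in
                      (counts.tp, counts.fp, counts.tn, counts.fn))
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    precision, flag_p = _safe_div(tp, tp + fp)
    recall, flag_r = _safe_div(tp, tp + fn)
    f1, flag_f = _safe_div(2 * precision * recall, precision + recall)
    table = pd.DataFrame({
        "accuracy": accuracy, "precision": precision, "recall": recall,
        "f1": f1, "degenerate": flag_p | flag_r | flag_f,
    })
    macro = table[["accuracy", "precision", "recall", "f1"]].mean()
    macro["degenerate"] = bool(table["degenerate"].any())
    table.loc["macro"] = macro
    return table


# -- ROC / AUC -------------------------------------------------------------

def roc_curve(scores: np.ndarray, truth: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(FPR, TPR, thresholds) with tied scores grouped into one step."""
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if scores.shape != truth.shape:
        raise EvaluationError("scores and truth lengths differ")
    n_pos = truth.sum()
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC needs at least one positive and one "
                              "negative sample")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], truth[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thresholds


def roc_auc(scores: np.ndarray, truth: np.ndarray
            ) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC curve points and trapezoidal AUC (= Mann–Whitney statistic)."""
    fpr, tpr, _ = roc_curve(scores, truth)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr), auc


def micro_roc_auc(probs: np.ndarray, Y: np.ndarray) -> float:
    """AUC on all (sample, label) pairs pooled across labels."""
    return roc_auc(np.asarray(probs).ravel(), np.asarray(Y).ravel())[1]


def macro_auc(probs: np.ndarray, Y: np.ndarray) -> float:
    """Mean of per-label AUCs."""
    probs, Y = np.atleast_2d(probs), np.atleast_2d(Y)
    return float(np.mean([roc_auc(probs[:, j], Y[:, j])[1]
                          for j in range(Y.shape[1])]))


def evaluate_probabilities(probs: np.ndarray, Y: np.ndarray,
                           threshold: float = 0.5) -> dict:
    """Aggregate metric dict used by cross-validation and the CLI."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    pred = predict_labels(probs, threshold)
    table = basic_metrics(confusion(pred, Y))
    macro = table.loc["macro"]
    aucs = {}
    for j in range(Y.shape[1]):
        col = Y[:, j]
        aucs[j] = (roc_auc(probs[:, j], col)[1]
                   if 0 < col.sum() < len(col) else np.nan)
    out = {
        "accuracy": float(macro["accuracy"]),
        "precision": float(macro["precision"]),
        "recall": float(macro["recall"]),
        "f1": float(macro["f1"]),
        "subset_accuracy": float((pred == Y).all(axis=1).mean()),
        "micro_auc": (micro_roc_auc(probs, Y)
                      if 0 < Y.sum() < Y.size else np.nan),
        "macro_auc": float(np.nanmean(list(aucs.values()))),
    }
    for j in range(Y.shape[1]):
        out[f"f1_label_{j}"] = float(table.loc[j, "f1"])
        out[f"auc_label_{j}"] = float(aucs[j])
    return out


# -- paired model comparison ----------------------------------------------

def paired_comparison(runs_a, runs_b) -> tuple[float, float]:
    """Two-sided paired t-test on matched metric runs.

    Returns (mean difference a-b, p value).  Zero-variance differences
    are degenerate: p = 1.0 when the mean difference is 0, else nan.
    """
    a = np.asarray(runs_a, dtype=float)
    b = np.asarray(runs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise EvaluationError("need >= 2 equal-length paired runs")
    diff = a - b
    mean_diff = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        return mean_diff, (1.0 if np.isclose(mean_diff, 0.0) else float("nan"))
    res = stats.ttest_rel(a, b)
    return mean_diff, float(res.pvalue)


# -- hyperparameter sweep ---------------------------------------------------

#: sweep keys resolved against TrainConfig vs ModelConfig
_TRAIN_KEYS = {"learning_rate", "batch_size", "epochs"}
_MODEL_KEYS = {"dropout_p", "n_heads", "hidden_dim", "token_dim"}


def sweep(grid: dict[str, list], X: np.ndarray, Y: np.ndarray,
          X_val: np.ndarray, Y_val: np.ndarray,
          model_config: ModelConfig, train_config, seed: int = 0
          ) -> pd.DataFrame:
    """One-factor-at-a-time hyperparameter sweep.

    Each grid entry varies a single setting around the base configs,
    trains on (X, Y) and scores on (X_val, Y_val); rows report
    accuracy, recall, precision, F1 and micro AUC per setting.
    """
    from .training import TrainConfig, train  # local: avoid cycle

    if not grid:
        raise EvaluationError("sweep grid is empty")
    for key in grid:
        if key not in _TRAIN_KEYS | _MODEL_KEYS:
            raise EvaluationError(f"unknown sweep hyperparameter {key!r}")
    rows = []
    for key, values in grid.items():
        for value in values:
            mc, tc = model_config, train_config
            if key in _TRAIN_KEYS:
                tc = replace(tc, **{key: value})
            else:
                mc = replace(mc, **{key: value})
            tc = replace(tc, seed=seed)
            params, _ = train(X, Y, mc, tc)
            probs, _ = forward(X_val, params, mc, mode="eval")
            m = evaluate_probabilities(probs, Y_val,
                                       threshold=mc.decision_threshold)
            rows.append({"hyperparameter": key, "value": value,
                         "accuracy": m["accuracy"], "recall": m["recall"],
                         "precision": m["precision"], "f1": m["f1"],
                         "auc": m["micro_auc"]})
    return pd.DataFrame(rows)


# -- permutation feature importance ----------------------------------------

def permutation_importance(params, X: np.ndarray, Y: np.ndarray,
                           config: ModelConfig, column_names=None,
                           repeats: int = 5, seed: int = 0) -> pd.DataFrame:
    """Mean micro-AUC drop when one encoded column is permuted.

    The model is evaluated once on intact data, then ``repeats`` times
    per column with that column's values shuffled across patients; the
    importance score is the mean AUC drop.  Output is sorted descending.
    """
    if repeats < 1:
        raise EvaluationError("repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    probs, _ = forward(X, params, config, mode="eval")
    base = micro_roc_auc(probs, Y)
    rng = np.random.default_rng(seed)
    names = (list(column_names) if column_names is not None
             else [f"col_{j}" for j in range(X.shape[1])])
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drops = []
        for _ in range(repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            p, _ = forward(Xp, params, config, mode="eval")
            drops.append(base - micro_roc_auc(p, Y))
        scores[j] = np.mean(drops)
    out = pd.DataFrame({"feature": names, "importance": scores,
                        "baseline_auc": base, "seed": seed})
    return out.sort_values("importance", ascending=False,
                           kind="stable").reset_index(drop=True)
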