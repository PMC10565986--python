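"""Cross-validated and thresholded evaluation of driver predictions.

Metrics follow the standard conventions: ROC-AUC is the Mann–Whitney
concordance probability (ties get half credit); PR-AUC is the step-wise area
under the precision–recall curve swept in descending score order (no
interpolation).  The decision threshold is the Youden-index cutoff —
the score maximizing sensitivity + specificity − 1 — averaged over repeated
cross-validation trials, mirroring a protocol in which each of ``trials``
independently seeded stratified k-fold runs contributes one threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .dataset import FeatureMatrix
from .model import GridSpec, predict_scores, small_grid, train_classifier

__all__ = [
    "EvaluationReport",
    "TrialResult",
    "roc_auc",
    "pr_auc",
    "youden_threshold",
    "classification_metrics",
    "crossval",
]


def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """Pairwise concordance probability (ties counted 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def pr_auc(scores, labels) -> float:
    """Step-wise area under the precision–recall curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.any(labels == 1):
        raise ValueError("PR-AUC requires at least one positive")
    return float(average_precision_score(labels, scores))


def youden_threshold(scores, labels) -> float:
    """Cutoff maximizing sensitivity + specificity − 1.

    Candidates are the minimum score (predict everything positive) and the
    midpoints between adjacent distinct scores; prediction is positive iff
    score >= threshold.  Ties break toward the LOWER threshold (higher
    sensitivity).  If all scores are equal the common score is returned with
    a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    distinct = np.unique(scores)
    if distinct.size == 1:
        warnings.warn("all scores identical; Youden threshold is degenerate")
        return float(distinct[0])
    candidates = np.concatenate(([distinct[0]], (distinct[:-1] + distinct[1:]) / 2.0))
    pos = labels == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    best_t, best_j = None, -np.inf
    for t in candidates:
        pred = scores >= t
        tpr = (pred & pos).sum() / n_pos
        fpr = (pred & ~pos).sum() / n_neg
        j = tpr - fpr
        if j > best_j:  # strict: ties keep the earlier (lower) threshold
            best_j, best_t = j, float(t)
    return best_t


def classification_metrics(scores, labels, threshold: float) -> dict:
    """Accuracy / precision / recall / F1 at ``score >= threshold``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred = scores >= threshold
    pos = labels == 1
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    n = tp + fp + fn + tn
    precision_undefined = (tp + fp) == 0
    precision = 0.0 if precision_undefined else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    f1 = (
        0.0
        if (precision + recall) == 0
        else 2 * precision * recall / (precision + recall)
    )
    return {
        "accuracy": (tp + tn) / n,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "precision_undefined": precision_undefined,
    }


@dataclass
class TrialResult:
    seed: int
    fold_roc_aucs: list[float]
    fold_pr_aucs: list[float]
    threshold: float  # Youden cutoff on pooled out-of-fold scores

    @property
    def mean_roc_auc(self) -> float:
        return float(np.mean(self.fold_roc_aucs))

    @property
    def mean_pr_auc(self) -> float:
        return float(np.mean(self.fold_pr_aucs))


@dataclass
class EvaluationReport:
    k: int
    trials: list[TrialResult]
    mean_roc_auc: float
    mean_pr_auc: float
    mean_threshold: float
    thresholded: dict  # metrics at the averaged threshold, averaged over trials

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n_trials": len(self.trials),
            "mean_roc_auc": self.mean_roc_auc,
            "mean_pr_auc": self.mean_pr_auc,
            "mean_threshold": self.mean_threshold,
            "thresholded": self.thresholded,
            "trials": [
                {
                    "seed": t.seed,
                    "fold_roc_aucs": t.fold_roc_aucs,
                    "fold_pr_aucs": t.fold_pr_aucs,
                    "threshold": t.threshold,
                }
                for t in self.trials
            ],
        }


def crossval(
    features,
    labels=None,
    k: int = 5,
    trials: int = 3,
    seed: int = 0,
    grid: GridSpec | None = None,
) -> EvaluationReport:
    """Repeated stratified k-fold cross-validation of the full classifier.

    Each trial draws its own fold partition from a trial seed derived from
    the master seed, trains a (grid-searched) random forest per fold with
    imputation means fit on the training fold only, and records per-fold
    ROC-AUC / PR-AUC plus the Youden threshold of the pooled out-of-fold
    scores.  ``grid`` defaults to a single standard combination; pass
    :func:`drivernet.model.default_grid` for the full search.
    """
    if isinstance(features, FeatureMatrix):
        Xdf, y = features.X, features.y
    else:
        if labels is None:
            raise ValueError("labels required when features is not a FeatureMatrix")
        Xdf, y = pd.DataFrame(features), np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    _check_two_classes(y)
    if min(np.bincount(y)) < k:
        raise ValueError("a class is too small for stratified k-fold")
    grid = grid or small_grid()

    trial_results = []
    trial_oof = []
    for t in range(trials):
        trial_seed = (seed * 1009 + t) % (2**31 - 1)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=trial_seed)
        fold_rocs, fold_prs = [], []
        oof_scores = np.full(len(y), np.nan)
        for train_idx, val_idx in skf.split(Xdf, y):
            X_train = Xdf.iloc[train_idx]
            X_val = Xdf.iloc[val_idx]
            means = X_train.mean(axis=0, skipna=True).fillna(0.0)
            X_train = X_train.fillna(means)
            X_val = X_val.fillna(means)
            m = train_classifier(X_train, grid=grid, seed=trial_seed, y=y[train_idx])
            s = predict_scores(m, X_val)
            oof_scores[val_idx] = s
            fold_rocs.append(roc_auc(s, y[val_idx]))
            fold_prs.append(pr_auc(s, y[val_idx]))
        threshold = youden_threshold(oof_scores, y)
        trial_results.append(TrialResult(trial_seed, fold_rocs, fold_prs, threshold))
        trial_oof.append(oof_scores)

    mean_threshold = float(np.mean([t.threshold for t in trial_results]))
    # thresholded metrics: each trial's out-of-fold scores evaluated at the
    # trial-averaged cutoff, then the metric (not the scores) averaged
    per_trial_metrics = [
        classification_metrics(oof, y, mean_threshold) for oof in trial_oof
    ]
    thresholded = {
        key: float(np.mean([m[key] for m in per_trial_metrics]))
        for key in ("accuracy", "precision", "recall", "f1")
    }
    return EvaluationReport(
        k=k,
        trials=trial_results,
        mean_roc_auc=float(np.mean([t.mean_roc_auc for t in trial_results])),
        mean_pr_auc=float(np.mean([t.mean_pr_auc for t in trial_results])),
        mean_threshold=mean_threshold,
        thresholded=thresholded,
    )
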