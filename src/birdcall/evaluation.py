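"""Multiclass evaluation: accuracy, precision/recall/F1, pairwise AUC,
top-5 accuracy, average precision / mAP, ROC curves, PCA embedding.

All metrics are computed one-vs-rest from an (n_samples, n_species) score
matrix whose rows are softmax posteriors.  AUC uses the pairwise-indicator
estimator

    AUC = sum_{t0 in D0} sum_{t1 in D1} I[f(t0) < f(t1)] / (|D0| |D1|)

with ties credited 0.5 by default (``strict=True`` reproduces the bare
indicator).  Average precision is the precision-weighted recall staircase
AP = sum_s P(s) dR(s) over samples sorted by descending score, and mAP is
the unweighted mean of per-class APs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclasses.dataclass
class ConfusionCounts:
    """One-vs-rest counts per class: maps class label -> (TP, FP, FN, TN)."""

    counts: dict[object, tuple[int, int, int, int]]


@dataclasses.dataclass
class ScoreSet:
    scores: np.ndarray  # (n_samples, n_species), rows sum to 1
    truths: np.ndarray  # integer class indices


@dataclasses.dataclass
class MetricsReport:
    accuracy: float
    precision: float           # macro
    recall: float              # macro
    f1: float                  # macro
    auc: float                 # macro, pairwise estimator
    top5_accuracy: float
    map_score: float
    micro_auc: float
    per_class: pd.DataFrame    # precision, recall, f1, auc, ap per class

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in
             ("accuracy", "precision", "recall", "f1", "auc",
              "top5_accuracy", "map_score", "micro_auc")}
        return json.dumps(d, indent=2)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "summary.json").write_text(self.to_json())
        self.per_class.to_csv(directory / "per_class.csv", index=True)


def confusion_counts(predictions, truths, labels=None) -> ConfusionCounts:
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if len(predictions) != len(truths):
        raise ValueError("prediction/truth length mismatch")
    if labels is None:
        labels = np.unique(truths)
    else:
        labels = np.asarray(labels)
        unknown = set(np.unique(predictions)) | set(np.unique(truths))
        if not unknown <= set(labels.tolist()):
            raise ValueError("unknown label outside the provided label set")
    n = len(truths)
    out = {}
    for lab in labels:
        tp = int(np.sum((predictions == lab) & (truths == lab)))
        fp = int(np.sum((predictions == lab) & (truths != lab)))
        fn = int(np.sum((predictions != lab) & (truths == lab)))
        out[lab] = (tp, fp, fn, n - tp - fp - fn)
    return ConfusionCounts(out)


def prf1(c: ConfusionCounts) -> pd.DataFrame:
    """Per-class precision, recall, F1; 0/0 is resolved to 0."""
    rows = {}
    for lab, (tp, fp, fn, _tn) in c.counts.items():
        if tp + fp == 0 or tp + fn == 0:
            warnings.warn(f"degenerate counts for class {lab!r}; "
                          "reporting 0 for the undefined rates")
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        rows[lab] = {"precision": precision, "recall": recall, "f1": f1}
    return pd.DataFrame.from_dict(rows, orient="index")


def accuracy(predictions, truths) -> float:
    """Correct classifications over all classifications."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    return float(np.mean(predictions == truths))


def top5_accuracy(s: ScoreSet) -> float:
    """Fraction of samples whose truth is among the 5 highest scores.

    Ties at the fifth rank are broken by ascending class index (stable
    sort on descending score)."""
    if s.scores.shape[1] < 5:
        raise ValueError("top-5 accuracy needs at least 5 classes")
    order = np.argsort(-s.scores, axis=1, kind="stable")
    top5 = order[:, :5]
    return float(np.mean(np.any(top5 == s.truths[:, None], axis=1)))


def auc_pairwise(scores_for_class, is_positive, strict: bool = False) -> float:
    """Pairwise-indicator AUC for one class.

    ``strict=True`` uses the bare indicator I[f(t0) < f(t1)]; the default
    credits ties 0.5 so identical scores give AUC = 0.5.
    """
    f = np.asarray(scores_for_class, dtype=float)
    pos = np.asarray(is_positive, dtype=bool)
    f1 = f[pos]
    f0 = f[~pos]
    if len(f1) == 0 or len(f0) == 0:
        raise ValueError("need at least one positive and one negative")
    diff = f1[:, None] - f0[None, :]
    wins = (diff > 0).sum()
    if strict:
        return float(wins / (len(f0) * len(f1)))
    ties = (diff == 0).sum()
    return float((wins + 0.5 * ties) / (len(f0) * len(f1)))


def macro_micro_auc(s: ScoreSet, strict: bool = False) -> tuple[float, float]:
    """Macro AUC (mean over classes with >= 1 positive) and micro AUC
    (all one-vs-rest (score, flag) pairs pooled)."""
    n_classes = s.scores.shape[1]
    aucs = []
    pooled_scores, pooled_flags = [], []
    for k in range(n_classes):
        flags = s.truths == k
        pooled_scores.append(s.scores[:, k])
        pooled_flags.append(flags)
        if flags.any() and (~flags).any():
            aucs.append(auc_pairwise(s.scores[:, k], flags, strict=strict))
        else:
            warnings.warn(f"class {k} lacks positives or negatives; "
                          "excluded from macro AUC")
    micro = auc_pairwise(np.concatenate(pooled_scores),
                         np.concatenate(pooled_flags), strict=strict)
    return float(np.mean(aucs)), micro


def average_precision(s: ScoreSet, k: int) -> float:
    """AP for class ``k``: sum over the descending-score ranking of
    precision-at-s times the change in recall."""
    flags = (s.truths == k).astype(float)
    n_pos = flags.sum()
    if n_pos == 0:
        raise ValueError(f"class {k} has no positives; AP undefined")
    order = np.argsort(-s.scores[:, k], kind="stable")
    hits = flags[order]
    csum = np.cumsum(hits)
    ranks = np.arange(1, len(hits) + 1)
    precision_at = csum / ranks
    delta_recall = hits / n_pos
    return float(np.sum(precision_at * delta_recall))


def map_score(s: ScoreSet) -> float:
    """Unweighted mean of per-class APs (classes with no positives are
    skipped with a warning)."""
    aps = []
    for k in range(s.scores.shape[1]):
        if not np.any(s.truths == k):
            warnings.warn(f"class {k} has no positives; skipped in mAP")
            continue
        aps.append(average_precision(s, k))
    return float(np.mean(aps))


def roc_curve(scores_for_class, is_positive):
    """(FPR, TPR) points at every distinct score threshold, from (0, 0)
    to (1, 1), both axes monotone non-decreasing."""
    f = np.asarray(scores_for_class, dtype=float)
    pos = np.asarray(is_positive, dtype=bool)
    n_pos, n_neg = pos.sum(), (~pos).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    order = np.argsort(-f, kind="stable")
    f_sorted = f[order]
    pos_sorted = pos[order]
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(~pos_sorted)
    # collapse runs of equal scores to their last index (threshold points)
    distinct = np.r_[np.flatnonzero(np.diff(f_sorted)), len(f_sorted) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return list(zip(fpr.tolist(), tpr.tolist()))


def micro_average_roc(s: ScoreSet):
    """ROC of all one-vs-rest (score, flag) pairs pooled across classes."""
    n_classes = s.scores.shape[1]
    scores = np.concatenate([s.scores[:, k] for k in range(n_classes)])
    flags = np.concatenate([s.truths == k for k in range(n_classes)])
    return roc_curve(scores, flags)


def macro_average_roc(s: ScoreSet, grid: int = 101):
    """Unweighted mean of per-class TPRs interpolated on a common FPR grid
    (classes lacking positives or negatives are skipped)."""
    fpr_grid = np.linspace(0.0, 1.0, grid)
    tprs = []
    for k in range(s.scores.shape[1]):
        flags = s.truths == k
        if not (flags.any() and (~flags).any()):
            continue
        fpr, tpr = np.array(roc_curve(s.scores[:, k], flags)).T
        tprs.append(np.interp(fpr_grid, fpr, tpr))
    if not tprs:
        raise ValueError("no class has both positives and negatives")
    return list(zip(fpr_grid.tolist(), np.mean(tprs, axis=0).tolist()))


def roc_auc_trapezoid(points) -> float:
    """Trapezoidal area under a :func:`roc_curve` point list."""
    fpr, tpr = np.array(points).T
    return float(np.trapezoid(tpr, fpr))


def pca_embed(matrices, n_components: int = 2) -> np.ndarray:
    """Mean-centred projection of flattened feature matrices onto the top
    principal axes; returns (n_samples, n_components) coordinates."""
    X = np.stack([np.asarray(m).ravel() for m in matrices])
    if len(X) <= n_components:
        raise ValueError("need more samples than components")
    return PCA(n_components=n_components, svd_solver="full").fit_transform(X)


def evaluate_scores(scores: np.ndarray, truths: np.ndarray,
                    strict_auc: bool = False) -> MetricsReport:
    """Assemble the full seven-metric report from posterior scores."""
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths)
    if len(scores) == 0:
        raise ValueError("empty evaluation set")
    s = ScoreSet(scores=scores, truths=truths)
    predictions = np.argmax(scores, axis=1)
    labels = np.arange(scores.shape[1])
    counts = confusion_counts(predictions, truths, labels=labels)
    table = prf1(counts)
    per_class_auc, per_class_ap = {}, {}
    for k in labels:
        flags = truths == k
        if flags.any() and (~flags).any():
            per_class_auc[k] = auc_pairwise(scores[:, k], flags,
                                            strict=strict_auc)
        else:
            per_class_auc[k] = np.nan
        per_class_ap[k] = (average_precision(s, k) if flags.any()
                           else np.nan)
    table["auc"] = pd.Series(per_class_auc)
    table["ap"] = pd.Series(per_class_ap)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        macro_auc, micro_auc = macro_micro_auc(s, strict=strict_auc)
        mapv = map_score(s)
    if scores.shape[1] >= 5:
        top5 = top5_accuracy(s)
    else:
        warnings.warn("fewer than 5 classes: top-5 accuracy undefined")
        top5 = float("nan")
    present = np.unique(truths)
    macro = table.loc[present]
    return MetricsReport(
        accuracy=accuracy(predictions, truths),
        precision=float(macro["precision"].mean()),
        recall=float(macro["recall"].mean()),
        f1=float(macro["f1"].mean()),
        auc=macro_auc,
        top5_accuracy=top5,
        map_score=mapv,
        micro_auc=micro_auc,
        per_class=table,
    )


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray,
             time_pool: int = 1) -> MetricsReport:
    """Score a trained model on featurized test data and report all
    seven metrics."""
    from .training import pool_time

    if len(X_test) == 0:
        raise ValueError("empty test set")
    scores = model.predict_proba(pool_time(np.asarray(X_test), time_pool))
    return evaluate_scores(scores, np.asarray(y_test))
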