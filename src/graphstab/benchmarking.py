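"""Cross-validated benchmarking with class rebalancing and the full metric suite.

Stratified K-fold (five splits by default) with disjoint test sets; random
oversampling of the minority class applied strictly *within* each training
fold, never to test data.  Per-fold metrics: precision, recall, false
positive rate, F1, Matthews correlation coefficient, ROC AUC, PRC AUC, the
confusion counts at the optimal threshold, and the optimal threshold itself
(Youden's J).  Fold means are unweighted arithmetic means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc, precision_recall_curve, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .graphs import ProteinGraph
from .nn import GraphStabilityClassifier

METRIC_NAMES = [
    "optimal_threshold",
    "precision",
    "recall",
    "fpr",
    "f1",
    "mcc",
    "roc_auc",
    "prc_auc",
]


@dataclass
class FoldPlan:
    """K disjoint test index sets + per-fold oversampled training multisets."""

    test_indices: list[np.ndarray]
    train_indices: list[np.ndarray]  # after oversampling (multisets)
    seed: int

    @property
    def k(self) -> int:
        return len(self.test_indices)


def stratified_kfold(labels: Sequence[int], k: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded stratified K-fold plan with within-fold minority oversampling.

    Test folds partition the dataset; each fold's training multiset is the
    complement of its test fold, with minority-class indices re-sampled with
    replacement until class counts are equal.
    """
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes present to stratify")
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small} has only {counts.min()} members (< k={k}); "
            "consider augmenting with generated decoys"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    test_sets, train_sets = [], []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        train_sets.append(oversample_training(train_idx, y, rng))
        test_sets.append(np.sort(test_idx))
    return FoldPlan(test_indices=test_sets, train_indices=train_sets, seed=seed)


def oversample_training(
    train_indices: Sequence[int],
    labels: Sequence[int],
    seed_or_rng=0,
) -> np.ndarray:
    """Random-oversample the minority class among ``train_indices``.

    Minority indices are re-sampled with replacement until class counts are
    equal; the majority class is untouched.  Already-balanced input is
    returned unchanged.  Test data never passes through here.
    """
    idx = np.asarray(train_indices, dtype=int)
    y = np.asarray(labels, dtype=int)[idx]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling requires both classes in the training set")
    if counts[0] == counts[1]:
        return idx.copy()
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    minority = classes[counts.argmin()]
    min_idx = idx[y == minority]
    deficit = counts.max() - counts.min()
    extra = rng.choice(min_idx, size=deficit, replace=True)
    return np.concatenate([idx, extra])


def _confusion(labels: np.ndarray, probabilities: np.ndarray, threshold: float):
    pred = probabilities >= threshold  # boundary counts positive
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fp, tn, fn


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"degenerate denominator for {name}; reporting 0")
        return 0.0
    return num / den


def mcc_from_confusion(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 (with warning) if any marginal is empty."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("degenerate denominator for mcc; reporting 0")
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def compute_metrics(
    labels: Sequence[int],
    probabilities: Sequence[float],
    threshold: float = 0.5,
) -> dict[str, float]:
    """One metric row at a fixed decision threshold.

    Thresholded metrics use ``probability >= threshold``; ROC AUC is the
    trapezoidal area under the full ROC curve and PRC AUC the trapezoidal
    area under the precision-recall curve.  Degenerate denominators yield 0
    with a warning so small folds stay aggregable.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities differ in shape")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("metrics need both classes present")
    tp, fp, tn, fn = _confusion(y, p, threshold)
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    fpr = _safe_div(fp, fp + tn, "fpr")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    mcc = mcc_from_confusion(tp, fp, tn, fn)
    roc = float(roc_auc_score(y, p))
    prec_curve, rec_curve, _ = precision_recall_curve(y, p)
    prc = float(auc(rec_curve, prec_curve))
    return {
        "threshold": float(threshold),
        "precision": float(precision),
        "recall": float(recall),
        "fpr": float(fpr),
        "f1": float(f1),
        "mcc": float(mcc),
        "roc_auc": roc,
        "prc_auc": prc,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def find_optimal_threshold(labels: Sequence[int], probabilities: Sequence[float]) -> float:
    """Threshold maximizing Youden's J = recall − FPR.

    Candidates are the observed probabilities (the only values at which the
    confusion matrix can change); ties resolve to the smallest qualifying
    threshold.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("optimal threshold needs both classes present")
    candidates = np.unique(p)
    best_thr, best_j = None, -np.inf
    for thr in candidates:  # ascending; strict > keeps the smallest tie
        tp, fp, tn, fn = _confusion(y, p, thr)
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        fpr = fp / (fp + tn) if (fp + tn) else 0.0
        j = recall - fpr
        if j > best_j:
            best_j, best_thr = j, float(thr)
    if best_j <= 0:
        warnings.warn("no threshold separates the classes (Youden's J <= 0)")
    return best_thr


@dataclass
class MetricsReport:
    """Per-fold rows plus their unweighted mean."""

    per_fold: pd.DataFrame
    mean: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mean is None:
            self.mean = self.per_fold.drop(columns=["fold"]).mean(axis=0)

    def to_csv(self, path) -> None:
        df = self.per_fold.copy()
        mean_row = self.mean.copy()
        mean_row["fold"] = "mean"
        df = pd.concat([df, mean_row.to_frame().T], ignore_index=True)
        df.to_csv(path, index=False)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "per_fold": self.per_fold.to_dict(orient="records"),
                "mean": self.mean.to_dict(),
            },
            default=float,
        )


def cross_validate(
    graphs: Sequence[ProteinGraph],
    labels: Sequence[int],
    k: int = 5,
    seed: int = 0,
    estimator: Optional[GraphStabilityClassifier] = None,
    collect_models: bool = False,
) -> MetricsReport:
    """Full benchmarking run: stratified K-fold, per-fold training with
    oversampled folds, metrics at each fold's optimal threshold.

    With ``collect_models`` the per-fold fitted estimators are attached to
    the report as ``report.models`` (for loss-curve inspection).
    """
    graphs = list(graphs)
    y = np.asarray(labels, dtype=int)
    plan = stratified_kfold(y, k=k, seed=seed)
    if estimator is None:
        estimator = GraphStabilityClassifier(seed=seed)
    rows = []
    models = []
    for fold, (tr, te) in enumerate(zip(plan.train_indices, plan.test_indices)):
        est = estimator.__class__(**{**estimator.get_params(), "seed": seed + fold})
        est.fit([graphs[i] for i in tr], y[tr])
        probs = est.predict_proba([graphs[i] for i in te])[:, 1]
        thr = find_optimal_threshold(y[te], probs)
        row = compute_metrics(y[te], probs, threshold=thr)
        row = {"fold": fold, "optimal_threshold": row.pop("threshold"), **row}
        rows.append(row)
        if collect_models:
            models.append(est)
    report = MetricsReport(per_fold=pd.DataFrame(rows))
    if collect_models:
        report.models = models
    return report
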