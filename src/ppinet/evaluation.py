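"""Performance evaluation: confusion metrics, cross-validation, PR curves,
and benchmark comparisons between prediction methods.

Metric definitions (on counts TP, FP, TN, FN):

* recall / true positive rate  TPR = TP / (TP + FN)
* false positive rate          FPR = FP / (FP + TN)
* precision                    P   = TP / (TP + FP)
* F1 = 2 P R / (P + R)

Benchmark comparison of a prediction method against an experimentally
determined pair set uses precision = overlap / total predictions and
recall = overlap / benchmark size, the convention of interactome
benchmarking tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .pairs import GoldStandardSet, Pair


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_scores(cls, scores, labels, threshold: float = 0.5) -> "ConfusionCounts":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=bool)
        called = scores >= threshold
        return cls(
            tp=int((called & labels).sum()),
            fp=int((called & ~labels).sum()),
            tn=int((~called & ~labels).sum()),
            fn=int((~called & labels).sum()),
        )


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """TPR, FPR, precision and F1 from counts; undefined ratios become NaN.

    F1 with precision + recall = 0 is reported as 0 (flagged via
    ``f1_defined``), the convention for degenerate benchmark rows.
    """

    def ratio(num: int, den: int) -> float:
        return float(Fraction(num, den)) if den else float("nan")

    tpr = ratio(counts.tp, counts.tp + counts.fn)
    fpr = ratio(counts.fp, counts.fp + counts.tn)
    precision = ratio(counts.tp, counts.tp + counts.fp)
    if np.isnan(precision) or np.isnan(tpr) or precision + tpr == 0:
        f1, f1_defined = 0.0, False
    else:
        f1, f1_defined = 2 * precision * tpr / (precision + tpr), True
    return {
        "tpr": tpr,
        "fpr": fpr,
        "precision": precision,
        "f1": f1,
        "f1_defined": f1_defined,
    }


def round_half_up(value: float, decimals: int) -> float:
    """Decimal rounding as printed in the comparison tables (half away from zero)."""
    factor = 10**decimals
    return float(np.floor(abs(value) * factor + 0.5) / factor * np.sign(value))


# ---------------------------------------------------------------------------
# PR curves


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    auc: float
    average_precision: float


def pr_curve(scores, labels) -> PRCurve:
    """Precision-recall curve with one point per distinct score threshold.

    Tied scores enter the positive set together (all-at-once threshold
    step).  AUC integrates precision over recall by the trapezoid rule;
    average precision (step-wise integral) is reported alongside.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("PR curve needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    cum_tp = np.cumsum(sorted_labels)
    cum_fp = np.cumsum(~sorted_labels)
    # indices where the score changes: thresholds include all tied items
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    idx = np.r_[distinct, sorted_labels.size - 1]
    recall = cum_tp[idx] / n_pos
    precision = cum_tp[idx] / (cum_tp[idx] + cum_fp[idx])
    # anchor at recall 0 with the precision of the top-scoring block so the
    # integral covers the full recall range
    recall = np.r_[0.0, recall]
    precision = np.r_[precision[0], precision]
    auc = float(np.trapezoid(precision, recall))
    # average precision: sum over recall increments of the precision there
    ap = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return PRCurve(recall=recall, precision=precision, auc=auc, average_precision=ap)


# ---------------------------------------------------------------------------
# k-fold cross-validation


def stratified_folds(labels, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified partition into k folds (indices)."""
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (True, False):
        idx = np.nonzero(labels == cls)[0]
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(int(j))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def kfold_cv(table, config=None, *, k: int = 10, seed: int = 0, threshold: float = 0.5) -> dict:
    """Stratified k-fold cross-validation of the interaction forest.

    Trains on k-1 folds, scores the held-out fold, and averages TPR, FPR,
    precision, F1 over folds; also pools the held-out scores for PR-AUC
    and ROC-AUC.  Every fold must contain both classes.
    """
    from sklearn.metrics import roc_auc_score

    from .model import ForestConfig, InteractionForest

    config = config or ForestConfig()
    labels = table.labels.to_numpy()
    folds = stratified_folds(labels, k, seed)
    per_fold = []
    pooled_scores = np.empty(len(labels))
    for fold_idx, test_idx in enumerate(folds):
        if labels[test_idx].all() or not labels[test_idx].any():
            raise ValueError(f"fold {fold_idx} lost a class; reduce k")
        train_mask = np.ones(len(labels), dtype=bool)
        train_mask[test_idx] = False
        results = InteractionForest(table.subset(train_mask), config).fit()
        scores = results.predict_scores(table.features.iloc[test_idx])
        pooled_scores[test_idx] = scores
        counts = ConfusionCounts.from_scores(scores, labels[test_idx], threshold)
        per_fold.append(confusion_metrics(counts))
    averaged = {
        key: float(np.nanmean([m[key] for m in per_fold]))
        for key in ("tpr", "fpr", "precision", "f1")
    }
    curve = pr_curve(pooled_scores, labels)
    averaged["pr_auc"] = curve.auc
    averaged["average_precision"] = curve.average_precision
    averaged["roc_auc"] = float(roc_auc_score(labels, pooled_scores))
    averaged["per_fold"] = per_fold
    averaged["k"] = k
    return averaged


# ---------------------------------------------------------------------------
# method comparison tables


@dataclass
class MethodComparison:
    table: pd.DataFrame  # per-method overlap, totals, precision, recall, F1
    benchmark_size: int


def compare_methods(
    benchmark: GoldStandardSet | set[Pair] | int,
    predictions: dict[str, set[Pair] | tuple[int, int]],
) -> MethodComparison:
    """Benchmark several prediction methods against one experimental pair set.

    ``predictions`` maps a method name either to its predicted pair set
    (overlap computed by set intersection) or to printed summary counts
    ``(overlap, total_predictions)`` when only the published tallies are
    available.  ``benchmark`` is correspondingly a pair set or its size.
    """
    if isinstance(benchmark, GoldStandardSet):
        bench_pairs: set[Pair] | None = benchmark.positives
    elif isinstance(benchmark, set):
        bench_pairs = benchmark
    else:
        bench_pairs = None
    bench_size = len(bench_pairs) if bench_pairs is not None else int(benchmark)
    if bench_size == 0:
        raise ValueError("benchmark is empty")
    rows = []
    for method, pred in predictions.items():
        if isinstance(pred, tuple):
            overlap, total = pred
        else:
            if bench_pairs is None:
                raise ValueError("pair-set predictions need a pair-set benchmark")
            overlap, total = len(pred & bench_pairs), len(pred)
        if overlap > min(total, bench_size):
            raise ValueError(f"{method}: overlap exceeds predictions or benchmark")
        precision = overlap / total if total else float("nan")
        recall = overlap / bench_size
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        rows.append(
            {
                "method": method,
                "positive_ppis": overlap,
                "all_predicted": total,
                "precision": precision,
                "recall": recall,
                "f1": f1,
            }
        )
    return MethodComparison(
        table=pd.DataFrame(rows).set_index("method"), benchmark_size=bench_size
    )
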