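"""Classifier training and evaluation on CSM feature representations.

Three classifier families are supported — k-nearest neighbours (Euclidean
distance on the representation in use), Gaussian naive Bayes, and random
forests — evaluated with seeded stratified 10-fold cross-validation.
Predictions from all folds are pooled into a single confusion matrix, from
which per-class precision, recall and F1 are computed, plus one-vs-rest AUC
when the classifier exposes class scores.  Weighted averages use class
support as weights.

Undefined precision (a class never predicted) is reported as 0 and flagged,
keeping weighted averages defined.  Micro-averaged precision, recall and
accuracy coincide for pooled single-label multiclass confusion matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from .datasets import LabeledDataset
from .errors import ComparisonError, StratificationError

ALGORITHMS = ("knn", "naive_bayes", "random_forest")

#: Default KNN neighbour grid for hyperparameter tuning.
DEFAULT_KNN_GRID = (1, 3, 5, 7, 9)


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm choice plus hyperparameters and the evaluation seed."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        valid = {
            "knn": {"k_nn"},
            "naive_bayes": {"var_smoothing"},
            "random_forest": {"n_trees", "max_features"},
        }[self.algorithm]
        unknown = set(self.hyperparameters) - valid
        if unknown:
            raise ValueError(
                f"invalid hyperparameters for {self.algorithm}: {sorted(unknown)}"
            )


def _make_estimator(spec: ClassifierSpec):
    hp = spec.hyperparameters
    if spec.algorithm == "knn":
        return KNeighborsClassifier(
            n_neighbors=int(hp.get("k_nn", 5)), metric="euclidean"
        )
    if spec.algorithm == "naive_bayes":
        # variance floor on per-class Gaussians; counts can be degenerate
        return GaussianNB(var_smoothing=float(hp.get("var_smoothing", 1e-9)))
    return RandomForestClassifier(
        n_estimators=int(hp.get("n_trees", 100)),
        max_features=hp.get("max_features", "sqrt"),
        random_state=spec.seed,
    )


@dataclass
class MetricsReport:
    """Per-class and weighted precision/recall/F1/AUC from pooled predictions."""

    classes: list[str]
    per_class: dict  # class -> {precision, recall, f1, auc, support}
    weighted_avg: dict  # {precision, recall, f1, auc}
    confusion: np.ndarray  # rows = true class, columns = predicted
    folds: int
    seed: int
    undefined_precision: list[str] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "per_class": self.per_class,
            "weighted_avg": self.weighted_avg,
            "confusion": self.confusion.tolist(),
            "folds": self.folds,
            "seed": self.seed,
            "undefined_precision": self.undefined_precision,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def __str__(self) -> str:
        lines = [f"{'class':<24s} {'prec':>6s} {'rec':>6s} {'F1':>6s} {'AUC':>6s} {'n':>5s}"]
        for cls in self.classes:
            m = self.per_class[cls]
            auc = f"{m['auc']:.3f}" if m.get("auc") is not None else "   - "
            lines.append(
                f"{cls:<24.24s} {m['precision']:6.3f} {m['recall']:6.3f} "
                f"{m['f1']:6.3f} {auc:>6s} {m['support']:5d}"
            )
        w = self.weighted_avg
        auc = f"{w['auc']:.3f}" if w.get("auc") is not None else "   - "
        lines.append(
            f"{'weighted avg':<24s} {w['precision']:6.3f} {w['recall']:6.3f} "
            f"{w['f1']:6.3f} {auc:>6s} {int(self.confusion.sum()):5d}"
        )
        return "\n".join(lines)


def compute_metrics(
    confusion: np.ndarray,
    classes: Sequence[str],
    y_true: Sequence | None = None,
    scores: np.ndarray | None = None,
    folds: int = 1,
    seed: int = 0,
) -> MetricsReport:
    """Precision/recall/F1 (and AUC when scores are given) from a confusion matrix.

    ``confusion[i, j]`` counts rows of true class i predicted as class j.
    Per class: precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their
    harmonic mean; 0/0 is defined as 0 and the class flagged.  AUC is
    one-vs-rest, computed from ``scores`` (samples × classes) against
    ``y_true``, and omitted otherwise.  Weighted averages are support-
    weighted means of the per-class values.
    """
    C = np.asarray(confusion)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {C.shape}")
    if C.shape[0] != len(classes):
        raise ValueError("class list must match confusion dimension")
    classes = [str(c) for c in classes]
    tp = np.diag(C).astype(float)
    support = C.sum(axis=1).astype(float)
    predicted = C.sum(axis=0).astype(float)

    undefined = []
    per_class: dict[str, dict] = {}
    aucs: dict[str, float] = {}
    if scores is not None and y_true is not None:
        y_true = np.asarray(y_true)
        for j, cls in enumerate(classes):
            mask = (y_true == cls).astype(int)
            if 0 < mask.sum() < len(mask):
                aucs[cls] = float(roc_auc_score(mask, scores[:, j]))
    for i, cls in enumerate(classes):
        if predicted[i] > 0:
            prec = tp[i] / predicted[i]
        else:
            prec = 0.0
            undefined.append(cls)
        rec = tp[i] / support[i] if support[i] > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        per_class[cls] = {
            "precision": float(prec),
            "recall": float(rec),
            "f1": float(f1),
            "auc": aucs.get(cls),
            "support": int(support[i]),
        }
    total = support.sum()
    weights = support / total if total > 0 else support
    weighted = {
        key: float(sum(per_class[c][key] * w for c, w in zip(classes, weights)))
        for key in ("precision", "recall", "f1")
    }
    if aucs:
        auc_w = np.array([support[classes.index(c)] for c in aucs])
        weighted["auc"] = float(
            sum(aucs[c] * w for c, w in zip(aucs, auc_w / auc_w.sum()))
        )
    else:
        weighted["auc"] = None
    return MetricsReport(
        classes=classes,
        per_class=per_class,
        weighted_avg=weighted,
        confusion=C,
        folds=folds,
        seed=seed,
        undefined_precision=undefined,
    )


def cross_validate(
    dataset: LabeledDataset,
    spec: ClassifierSpec,
    folds: int = 10,
    seed: int | None = None,
) -> MetricsReport:
    """Stratified k-fold cross-validation with a pooled confusion matrix.

    Fold assignment is deterministic given the seed; every row is predicted
    exactly once.  Classifiers exposing ``predict_proba`` (all three here;
    KNN scores are neighbour-vote fractions) also yield one-vs-rest AUC.
    """
    seed = spec.seed if seed is None else seed
    X = dataset.values
    y = np.asarray([str(v) for v in dataset.labels])
    classes = sorted(set(y.tolist()))
    counts = {c: int((y == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < folds]
    if small:
        raise StratificationError(
            f"classes smaller than {folds} folds: {small} "
            f"(counts {[counts[c] for c in small]})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty(len(y), dtype=object)
    scores = np.zeros((len(y), len(classes)))
    have_scores = True
    for train, test in skf.split(X, y):
        est = _make_estimator(replace(spec, seed=seed))
        est.fit(X[train], y[train])
        y_pred[test] = est.predict(X[test])
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X[test])
            col = {c: j for j, c in enumerate(est.classes_)}
            for j, cls in enumerate(classes):
                if cls in col:
                    scores[test, j] = proba[:, col[cls]]
        else:
            have_scores = False
    C = sk_confusion(y, y_pred.astype(str), labels=classes)
    return compute_metrics(
        C,
        classes,
        y_true=y if have_scores else None,
        scores=scores if have_scores else None,
        folds=folds,
        seed=seed,
    )


def tune_hyperparameters(
    dataset: LabeledDataset,
    grid: Sequence[ClassifierSpec],
    folds: int = 10,
    seed: int | None = None,
) -> tuple[ClassifierSpec, MetricsReport]:
    """Evaluate every spec with the same folds/seed and return the best.

    Best = highest weighted precision; ties broken by weighted F1, then by
    grid order.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("spec grid must be non-empty")
    best: tuple[float, float, int] | None = None
    best_pair: tuple[ClassifierSpec, MetricsReport] | None = None
    for order, spec in enumerate(grid):
        report = cross_validate(dataset, spec, folds=folds, seed=seed)
        key = (report.weighted_avg["precision"], report.weighted_avg["f1"], -order)
        if best is None or key > best:
            best = key
            best_pair = (spec, report)
    assert best_pair is not None
    return best_pair


def format_delta(before: float, after: float) -> str:
    """Percentage-point difference formatted like '+9.0%' (0.901 → 0.991)."""
    delta = (after - before) * 100.0
    return f"{delta:+.1f}%"


def compare_runs(report_a: MetricsReport, report_b: MetricsReport) -> dict:
    """Per-class and weighted precision/recall deltas (a → b), as pct points.

    Returns a mapping class → {"precision_before", "precision_after",
    "delta_precision", ...} with a "weighted avg" entry; deltas use the
    '+9.0%' percentage-point format.
    """
    if set(report_a.classes) != set(report_b.classes):
        raise ComparisonError(
            f"class sets differ: {sorted(report_a.classes)} vs {sorted(report_b.classes)}"
        )
    table: dict[str, dict] = {}
    rows = [(c, report_a.per_class[c], report_b.per_class[c]) for c in report_a.classes]
    rows.append(("weighted avg", report_a.weighted_avg, report_b.weighted_avg))
    for name, a, b in rows:
        table[name] = {
            "precision_before": a["precision"],
            "precision_after": b["precision"],
            "delta_precision": format_delta(a["precision"], b["precision"]),
            "recall_before": a["recall"],
            "recall_after": b["recall"],
            "delta_recall": format_delta(a["recall"], b["recall"]),
        }
    return table
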