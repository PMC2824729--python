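"""Benchmarking of prioritization against labeled disease/control genes.

Given a labeled universe (known disease genes as positives, genes from
regions never linked to disease as negatives) this module computes the
confusion matrix of a predicted-positive set, the derived
sensitivity/specificity/accuracy, an empirical ROC curve with trapezoid
AUC from continuous scores, the fold-enrichment ratio of the predicted
set, and side-by-side comparison tables for external prediction methods
whose outputs are ingested as plain ID lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkLabels",
    "ConfusionMatrix",
    "BenchmarkResult",
    "confusion",
    "metrics",
    "roc_curve",
    "enrichment_ratio",
    "comparison_table",
    "evaluate",
]


@dataclass(frozen=True)
class BenchmarkLabels:
    """Disjoint positive (disease) and negative (control) gene sets."""

    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positives or not self.negatives:
            raise ValueError("both label sets must be non-empty")
        if self.positives & self.negatives:
            raise ValueError(
                f"labels overlap: {sorted(self.positives & self.negatives)}"
            )

    @property
    def universe(self) -> frozenset[str]:
        return self.positives | self.negatives

    @property
    def n_disease(self) -> int:
        """ΣDG — all disease genes in the benchmark."""
        return len(self.positives)

    @property
    def n_total(self) -> int:
        """ΣG — total genes considered."""
        return len(self.positives) + len(self.negatives)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_predicted(self) -> int:
        return self.tp + self.fp


@dataclass
class BenchmarkResult:
    matrix: ConfusionMatrix
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    enrichment: float | None
    roc_points: list[tuple[float, float, float]] | None = None  # (thr, fpr, tpr)
    auc: float | None = None


def confusion(
    predicted_positive: Iterable[str], labels: BenchmarkLabels
) -> ConfusionMatrix:
    """Confusion matrix of a predicted-positive gene set.

    IDs outside the labeled universe are dropped with a warning — a
    genome-wide prediction list legitimately covers more genes than the
    benchmark.
    """
    predicted = set(predicted_positive)
    outside = predicted - labels.universe
    if outside:
        logger.warning(
            "%d predicted IDs outside the labeled universe ignored",
            len(outside),
        )
        predicted &= labels.universe
    tp = len(predicted & labels.positives)
    fp = len(predicted & labels.negatives)
    return ConfusionMatrix(
        tp=tp,
        fp=fp,
        tn=len(labels.negatives) - fp,
        fn=len(labels.positives) - tp,
    )


def metrics(
    matrix: ConfusionMatrix,
) -> tuple[float | None, float | None, float | None]:
    """(sensitivity, specificity, accuracy); ``None`` where undefined."""
    sens = (
        matrix.tp / (matrix.tp + matrix.fn)
        if matrix.tp + matrix.fn
        else None
    )
    spec = (
        matrix.tn / (matrix.tn + matrix.fp)
        if matrix.tn + matrix.fp
        else None
    )
    acc = (matrix.tp + matrix.tn) / matrix.total if matrix.total else None
    return sens, spec, acc


def roc_curve(
    scores: Mapping[str, float], labels: BenchmarkLabels
) -> tuple[list[tuple[float, float, float]], float]:
    """Empirical ROC from a threshold sweep over the distinct score values.

    Equal scores are grouped into a single threshold step so the curve does
    not depend on input order.  Genes missing from ``scores`` enter with
    score 0 (warned).  Returns ``(points, auc)`` where each point is
    ``(threshold, fpr, tpr)`` — the prediction at a threshold t is
    "score >= t" — and the AUC is the trapezoid-rule area, which equals the
    probability that a random positive outscores a random negative with
    ties counted half.
    """
    missing = labels.universe - set(scores)
    if missing:
        logger.warning("%d labeled genes without a score; scored 0", len(missing))
    y = []
    s = []
    for gene in sorted(labels.universe):
        y.append(1 if gene in labels.positives else 0)
        s.append(float(scores.get(gene, 0.0)))
    y_arr = np.asarray(y)
    s_arr = np.asarray(s)
    n_pos = int(y_arr.sum())
    n_neg = len(y_arr) - n_pos

    points: list[tuple[float, float, float]] = [(np.inf, 0.0, 0.0)]
    tp = fp = 0
    # sweep thresholds from the highest score down, one step per distinct value
    order = np.argsort(-s_arr, kind="stable")
    i = 0
    while i < len(order):
        thr = s_arr[order[i]]
        while i < len(order) and s_arr[order[i]] == thr:
            if y_arr[order[i]]:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append((float(thr), fp / n_neg, tp / n_pos))
    fprs = np.array([p[1] for p in points])
    tprs = np.array([p[2] for p in points])
    auc = float(np.trapezoid(tprs, fprs))
    return points, auc


def enrichment_ratio(
    matrix: ConfusionMatrix,
    labels: BenchmarkLabels,
    definition: str = "density",
) -> float | None:
    """Fold enrichment of disease genes in the predicted set.

    ``density`` (default): disease-gene density among predictions divided
    by the background density ΣDG/ΣG — the standard meaning of "fold
    enrichment"; it is 1 in expectation for a label-blind predictor.
    ``sensitivity``: the literal proportion-of-disease-genes-recovered
    reading, tp/ΣDG.  ``None`` when no positives were predicted.
    """
    if matrix.n_predicted == 0:
        return None
    if definition == "density":
        predicted_density = matrix.tp / matrix.n_predicted
        background = labels.n_disease / labels.n_total
        return predicted_density / background
    if definition == "sensitivity":
        return matrix.tp / labels.n_disease
    raise ValueError(f"unknown enrichment definition {definition!r}")


def evaluate(
    predicted_positive: Iterable[str],
    labels: BenchmarkLabels,
    scores: Mapping[str, float] | None = None,
    enrichment_def: str = "density",
) -> BenchmarkResult:
    """Full benchmark of one method: matrix, rates, enrichment, optional ROC."""
    matrix = confusion(predicted_positive, labels)
    sens, spec, acc = metrics(matrix)
    result = BenchmarkResult(
        matrix=matrix,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        enrichment=enrichment_ratio(matrix, labels, enrichment_def),
    )
    if scores is not None:
        result.roc_points, result.auc = roc_curve(scores, labels)
    return result


def comparison_table(
    predictions: Mapping[str, Iterable[str]], labels: BenchmarkLabels
) -> pd.DataFrame:
    """Accuracy/sensitivity/specificity (percent, 1 decimal) per method.

    One column per method, metric rows — the layout of published method
    comparisons.  A method whose file yielded no usable IDs gets NA cells.
    """
    cols: dict[str, list[float | None]] = {}
    for name, ids in predictions.items():
        ids = {i for i in ids if i}
        if not ids:
            logger.warning("method %s: no parsable IDs; reported as NA", name)
            cols[name] = [None, None, None]
            continue
        sens, spec, acc = metrics(confusion(ids, labels))
        cols[name] = [
            None if v is None else round(100 * v, 1)
            for v in (acc, sens, spec)
        ]
    return pd.DataFrame(
        cols, index=["Accuracy (%)", "Sensitivity (%)", "Specificity (%)"]
    )
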