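"""Partition-agreement and classification metrics.

Rand Index and Adjusted Rand Index are computed from the contingency
table by the pair-counting / permutation-model formulas; classification
quality uses a true-by-predicted confusion matrix with macro-averaged
one-vs-rest precision, recall, specificity and F1 (classes never
predicted contribute precision 0 so macro averages stay comparable
across runs with missing predicted classes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np

from .datatypes import PartitionLabels
from .errors import ValidationError


@dataclass(frozen=True)
class ClusteringScore:
    rand_index: float
    adjusted_rand_index: float
    n_items: int


@dataclass(frozen=True)
class ClassificationScore:
    confusion: np.ndarray         # rows = truth, columns = predicted
    class_order: tuple[str, ...]
    accuracy: float
    macro_recall: float
    macro_precision: float
    macro_specificity: float
    macro_f1: float


def _contingency(a: PartitionLabels, b: PartitionLabels) -> np.ndarray:
    ids_a = set(a.assignment)
    ids_b = set(b.assignment)
    if ids_a != ids_b:
        raise ValidationError("partitions cover different item sets")
    ids = sorted(ids_a)
    la = np.array([a.assignment[i] for i in ids])
    lb = np.array([b.assignment[i] for i in ids])
    table = np.zeros((la.max() + 1, lb.max() + 1), dtype=np.int64)
    np.add.at(table, (la, lb), 1)
    return table


def rand_and_adjusted(a: PartitionLabels, b: PartitionLabels) -> ClusteringScore:
    """RI = agreeing pairs / all pairs; ARI by the contingency formula."""
    table = _contingency(a, b)
    n = int(table.sum())
    if n < 2:
        raise ValidationError("need at least 2 items to compare partitions")
    total_pairs = comb(n, 2)
    sum_cells = int(sum(comb(int(x), 2) for x in table.ravel()))
    sum_rows = int(sum(comb(int(x), 2) for x in table.sum(axis=1)))
    sum_cols = int(sum(comb(int(x), 2) for x in table.sum(axis=0)))

    # pairs together in both + pairs separate in both
    ri = (total_pairs + 2 * sum_cells - sum_rows - sum_cols) / total_pairs

    expected = sum_rows * sum_cols / total_pairs
    denom = 0.5 * (sum_rows + sum_cols) - expected
    if denom == 0.0:
        # both partitions trivial (all-singletons or one cluster): perfect
        # agreement by convention
        ari = 1.0
    else:
        ari = (sum_cells - expected) / denom
    return ClusteringScore(rand_index=ri, adjusted_rand_index=ari, n_items=n)


def classification_scores(
    truth: Mapping[str, str],
    predicted: Mapping[str, str],
    class_order: Sequence[str] | None = None,
) -> ClassificationScore:
    """Confusion matrix plus accuracy and macro one-vs-rest scores."""
    if not truth:
        raise ValidationError("empty input")
    if set(truth) != set(predicted):
        raise ValidationError("truth and prediction cover different items")
    if class_order is None:
        class_order = sorted(set(truth.values()) | set(predicted.values()))
    classes = list(class_order)
    index = {c: i for i, c in enumerate(classes)}
    missing = [c for c in set(truth.values()) | set(predicted.values())
               if c not in index]
    if missing:
        raise ValidationError(f"classes not in class_order: {sorted(missing)}")

    n = len(truth)
    conf = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for item in truth:
        conf[index[truth[item]], index[predicted[item]]] += 1

    accuracy = float(np.trace(conf)) / n
    recalls, precisions, specificities, f1s = [], [], [], []
    for i in range(len(classes)):
        tp = float(conf[i, i])
        fn = float(conf[i, :].sum() - tp)
        fp = float(conf[:, i].sum() - tp)
        tn = float(n - tp - fn - fp)
        recalls.append(tp / (tp + fn) if tp + fn > 0 else 0.0)
        if tp + fp > 0:
            precisions.append(tp / (tp + fp))
        else:
            warnings.warn(
                f"class {classes[i]!r} never predicted; precision set to 0",
                stacklevel=2,
            )
            precisions.append(0.0)
        specificities.append(tn / (tn + fp) if tn + fp > 0 else 0.0)
        p, r = precisions[-1], recalls[-1]
        f1s.append(2 * p * r / (p + r) if p + r > 0 else 0.0)

    return ClassificationScore(
        confusion=conf,
        class_order=tuple(classes),
        accuracy=accuracy,
        macro_recall=float(np.mean(recalls)),
        macro_precision=float(np.mean(precisions)),
        macro_specificity=float(np.mean(specificities)),
        macro_f1=float(np.mean(f1s)),
    )
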