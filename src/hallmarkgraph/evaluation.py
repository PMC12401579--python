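"""Classifier test metrics and hierarchical validation metrics.

Per-classifier evaluation reports nine metrics -- accuracy, balanced
accuracy, weighted F1, micro and macro precision/recall/F1, macro AUROC and
macro AUPRC -- plus the confusion matrix and one-vs-rest ROC / precision-
recall curves.

Hierarchical validation scores a set of samples against reference label
paths at three granularities:

* separate accuracy: each tier scored independently;
* combined accuracy at tier k: correct only if tiers 1..k are all correct;
* sample-level accuracy: correct only if every defined reference tier is
  correct.

By construction combined <= separate per tier and sample-level <= combined
at the maximum depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    balanced_accuracy_score,
    confusion_matrix as sk_confusion_matrix,
    f1_score,
    precision_recall_curve,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    balanced_accuracy: float
    weighted_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_auroc: float
    macro_auprc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def confusion(
    y_true: Sequence, y_pred: Sequence, vocabulary: Sequence | None = None
) -> np.ndarray:
    """C x C count matrix, rows = true label, columns = predicted label."""
    labels = list(vocabulary) if vocabulary is not None else sorted(
        set(y_true) | set(y_pred)
    )
    return sk_confusion_matrix(y_true, y_pred, labels=labels)


def compute_metrics(
    y_true: Sequence,
    y_pred: Sequence,
    y_prob: np.ndarray | None = None,
    *,
    vocabulary: Sequence | None = None,
) -> MetricsReport:
    """All nine test metrics for single-label multiclass predictions.

    ``y_prob`` columns follow ``vocabulary`` order (sorted unique labels when
    not given).  Macro AUROC/AUPRC are one-vs-rest averages; a class absent
    from ``y_true`` has no defined one-vs-rest curve and is excluded from the
    macro average with a warning.  Without probabilities the two
    ranking metrics are reported as NaN.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    vocab = list(vocabulary) if vocabulary is not None else sorted(
        set(y_true) | set(y_pred)
    )
    auroc, auprc = np.nan, np.nan
    if y_prob is not None:
        y_prob = np.asarray(y_prob)
        if y_prob.shape != (len(y_true), len(vocab)):
            raise ValueError(
                f"y_prob shape {y_prob.shape} does not match "
                f"({len(y_true)}, {len(vocab)})"
            )
        auroc, auprc = _macro_ranking_metrics(y_true, y_prob, vocab)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division on absent classes
        return MetricsReport(
            accuracy=float(accuracy_score(y_true, y_pred)),
            balanced_accuracy=float(balanced_accuracy_score(y_true, y_pred)),
            weighted_f1=float(
                f1_score(y_true, y_pred, labels=vocab, average="weighted", zero_division=0)
            ),
            micro_precision=float(
                precision_score(y_true, y_pred, labels=vocab, average="micro", zero_division=0)
            ),
            micro_recall=float(
                recall_score(y_true, y_pred, labels=vocab, average="micro", zero_division=0)
            ),
            micro_f1=float(
                f1_score(y_true, y_pred, labels=vocab, average="micro", zero_division=0)
            ),
            macro_precision=float(
                precision_score(y_true, y_pred, labels=vocab, average="macro", zero_division=0)
            ),
            macro_recall=float(
                recall_score(y_true, y_pred, labels=vocab, average="macro", zero_division=0)
            ),
            macro_f1=float(
                f1_score(y_true, y_pred, labels=vocab, average="macro", zero_division=0)
            ),
            macro_auroc=auroc,
            macro_auprc=auprc,
        )


def _macro_ranking_metrics(
    y_true: np.ndarray, y_prob: np.ndarray, vocab: list
) -> tuple[float, float]:
    aurocs: list[float] = []
    auprcs: list[float] = []
    skipped: list = []
    for c, label in enumerate(vocab):
        pos = (y_true == label).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            skipped.append(label)
            continue
        aurocs.append(float(roc_auc_score(pos, y_prob[:, c])))
        auprcs.append(float(average_precision_score(pos, y_prob[:, c])))
    if skipped:
        warnings.warn(
            f"classes {skipped} have no positives (or no negatives) in y_true; "
            "excluded from macro AUROC/AUPRC",
            stacklevel=3,
        )
    if not aurocs:
        return np.nan, np.nan
    return float(np.mean(aurocs)), float(np.mean(auprcs))


def roc_prc_curves(
    y_true: Sequence,
    y_prob: np.ndarray,
    *,
    vocabulary: Sequence | None = None,
) -> dict:
    """One-vs-rest ROC and precision-recall curve points per class.

    Returns ``{label: {"roc": (fpr, tpr), "prc": (precision, recall),
    "auroc": a, "auprc": p}}`` plus macro areas under key ``"macro"``;
    the areas agree with :func:`compute_metrics` because both use the same
    one-vs-rest decomposition.
    """
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob)
    vocab = list(vocabulary) if vocabulary is not None else sorted(set(y_true))
    out: dict = {}
    aurocs, auprcs = [], []
    for c, label in enumerate(vocab):
        pos = (y_true == label).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            continue
        fpr, tpr, _ = roc_curve(pos, y_prob[:, c])
        precision, recall, _ = precision_recall_curve(pos, y_prob[:, c])
        a = float(roc_auc_score(pos, y_prob[:, c]))
        p = float(average_precision_score(pos, y_prob[:, c]))
        aurocs.append(a)
        auprcs.append(p)
        out[label] = {
            "roc": (fpr, tpr),
            "prc": (precision, recall),
            "auroc": a,
            "auprc": p,
        }
    out["macro"] = {
        "auroc": float(np.mean(aurocs)) if aurocs else np.nan,
        "auprc": float(np.mean(auprcs)) if auprcs else np.nan,
    }
    return out


# ---------------------------------------------------------------------------
# Hierarchical validation metrics
#
# ``predictions``: mapping level -> {sample_id: predicted tier-k label}.
# ``truth``: mapping sample_id -> reference label path (tuple of tier strings).


def separate_accuracy(
    predictions: Mapping[int, Mapping[str, str]],
    truth: Mapping[str, Sequence[str]],
) -> dict[int, float]:
    """Per-level accuracy, each tier scored independently.

    A sample enters the level-k denominator only if its reference path
    defines tier k and a level-k prediction exists for it.
    """
    out: dict[int, float] = {}
    for level, preds in sorted(predictions.items()):
        correct = total = 0
        for sid, pred in preds.items():
            ref = truth.get(sid)
            if ref is None or len(ref) < level:
                continue
            total += 1
            correct += pred == ref[level - 1]
        if total:
            out[level] = correct / total
    return out


def combined_accuracy(
    predictions: Mapping[int, Mapping[str, str]],
    truth: Mapping[str, Sequence[str]],
) -> dict[int, float]:
    """Per-level accuracy of the chained label prefix.

    A sample counts correct at level k only if its predicted tiers 1..k all
    equal the reference tiers 1..k; the denominator at level k is the set of
    samples with reference depth >= k and predictions at every level 1..k.
    """
    out: dict[int, float] = {}
    for level in sorted(predictions):
        correct = total = 0
        for sid, ref in truth.items():
            if len(ref) < level:
                continue
            chain = [
                predictions.get(k, {}).get(sid) for k in range(1, level + 1)
            ]
            if any(p is None for p in chain):
                continue
            total += 1
            correct += all(p == ref[k] for k, p in enumerate(chain))
        if total:
            out[level] = correct / total
    return out


def sample_level_accuracy(
    predictions: Mapping[int, Mapping[str, str]],
    truth: Mapping[str, Sequence[str]],
) -> float:
    """Fraction of samples whose every defined reference tier is predicted
    correctly by the corresponding per-level classifier."""
    correct = total = 0
    for sid, ref in truth.items():
        chain = [predictions.get(k, {}).get(sid) for k in range(1, len(ref) + 1)]
        if any(p is None for p in chain):
            continue
        total += 1
        correct += all(p == ref[k] for k, p in enumerate(chain))
    if total == 0:
        return float("nan")
    return correct / total


@dataclass(frozen=True)
class ValidationReport:
    """Hierarchical validation summary over a held-out (FALSE) sample set."""

    separate: dict[int, float]
    combined: dict[int, float]
    sample_level: float
    n_samples: int

    def as_dict(self) -> dict:
        return {
            "separate": {str(k): v for k, v in self.separate.items()},
            "combined": {str(k): v for k, v in self.combined.items()},
            "sample_level": self.sample_level,
            "n_samples": self.n_samples,
        }


def validate_hierarchy(
    predictions: Mapping[int, Mapping[str, str]],
    truth: Mapping[str, Sequence[str]],
) -> ValidationReport:
    return ValidationReport(
        separate=separate_accuracy(predictions, truth),
        combined=combined_accuracy(predictions, truth),
        sample_level=sample_level_accuracy(predictions, truth),
        n_samples=len(truth),
    )
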