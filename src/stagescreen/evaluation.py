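"""Leave-one-person-out cross-validation and the per-class metric suite.

Evaluation is subject-level: each child is held out once, the model is
retrained from scratch on everyone else, and the held-out prediction goes
into a single 3x3 confusion matrix (rows = true class, columns = predicted,
order NORMAL / ADHD_RISK / ADHD).  Per-class metrics use the one-vs-rest
reduction of that matrix:

    Acc = (TP+TN)/(TP+TN+FP+FN)      Se  = TP/(TP+FN)     Sp = TN/(TN+FP)
    F1  = 2TP/(2TP+FP+FN)            FNR = FN/(FN+TP)
    FPR = FP/(FP+TN)                 FDR = FP/(FP+TP)

Acc, Se, Sp and F1 are reported in percent; FPR, FDR and FNR as
proportions.  Reference lengths, class weights and everything else that
could leak label information are recomputed inside each training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .data import (
    LABELS,
    LABEL_INDEX,
    OverflowPolicy,
    PaddedStageBatch,
    SubjectSession,
    compute_reference_lengths,
    pad_sessions,
)
from .model import (
    AttentionProfile,
    ModelConfig,
    Prediction,
    StageAttentionClassifier,
    class_weights_from_counts,
)

__all__ = [
    "ConfusionMatrix3",
    "ClassMetrics",
    "MetricsReport",
    "CVResult",
    "lopo_split",
    "run_lopo",
    "metrics_from_confusion",
]

CLASS_NAMES = tuple(lab.value for lab in LABELS)


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 true-by-predicted counts, class order NORMAL, ADHD_RISK, ADHD."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            counts = counts.astype(np.int64)
            if np.any(counts < 0):
                raise ValueError("confusion matrix entries must be >= 0")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @classmethod
    def from_predictions(
        cls, true_labels: Sequence, predicted_labels: Sequence
    ) -> "ConfusionMatrix3":
        counts = np.zeros((3, 3), dtype=np.int64)
        for t, p in zip(true_labels, predicted_labels, strict=True):
            counts[LABEL_INDEX[t], LABEL_INDEX[p]] += 1
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, class_index: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for one class against the rest."""
        tp = int(self.counts[class_index, class_index])
        fn = int(self.counts[class_index].sum() - tp)
        fp = int(self.counts[:, class_index].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fp, fn, tn


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics for a single class.

    ``acc``, ``se``, ``sp``, ``f1`` are percents; ``fpr``, ``fdr``, ``fnr``
    proportions.  ``degenerate`` marks any metric whose denominator was
    zero (reported as 0 by convention).
    """

    acc: float
    se: float
    sp: float
    f1: float
    fpr: float
    fdr: float
    fnr: float
    degenerate: bool = False


@dataclass(frozen=True)
class MetricsReport:
    per_class: dict[str, ClassMetrics]
    overall_accuracy: float  # percent, trace/total * 100

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_class": {
                name: vars(m) for name, m in self.per_class.items()
            },
        }


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def metrics_from_confusion(cm: ConfusionMatrix3) -> MetricsReport:
    """Per-class one-vs-rest metrics plus the overall accuracy."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    per_class: dict[str, ClassMetrics] = {}
    for k, name in enumerate(CLASS_NAMES):
        tp, fp, fn, tn = cm.one_vs_rest(k)
        degenerate = False
        acc, d = _safe_div(tp + tn, tp + tn + fp + fn); degenerate |= d
        se, d = _safe_div(tp, tp + fn); degenerate |= d
        sp, d = _safe_div(tn, tn + fp); degenerate |= d
        f1, d = _safe_div(2 * tp, 2 * tp + fp + fn); degenerate |= d
        fpr, d = _safe_div(fp, fp + tn); degenerate |= d
        fdr, d = _safe_div(fp, fp + tp); degenerate |= d
        fnr, d = _safe_div(fn, fn + tp); degenerate |= d
        per_class[name] = ClassMetrics(
            acc=100.0 * acc,
            se=100.0 * se,
            sp=100.0 * sp,
            f1=100.0 * f1,
            fpr=fpr,
            fdr=fdr,
            fnr=fnr,
            degenerate=degenerate,
        )
    overall = 100.0 * np.trace(cm.counts) / cm.total
    return MetricsReport(per_class=per_class, overall_accuracy=float(overall))


@dataclass
class CVResult:
    """Aggregated leave-one-person-out outcome."""

    confusion: ConfusionMatrix3
    predictions: dict[str, Prediction]
    profiles: dict[str, AttentionProfile]
    labels: dict[str, object]  # subject_id -> Label

    @property
    def overall_accuracy(self) -> float:
        return 100.0 * np.trace(self.confusion.counts) / self.confusion.total


def lopo_split(
    sessions: Sequence[SubjectSession],
) -> list[tuple[list[SubjectSession], SubjectSession]]:
    """All (training set, held-out subject) folds; each subject out once."""
    if len(sessions) < 2:
        raise ValueError("leave-one-person-out needs at least 2 subjects")
    return [
        ([s for j, s in enumerate(sessions) if j != i], sessions[i])
        for i in range(len(sessions))
    ]


def run_lopo(
    sessions: Sequence[SubjectSession],
    config: ModelConfig,
    progress: Callable[[int, int], None] | None = None,
) -> CVResult:
    """Full leave-one-person-out evaluation.

    Per fold: padding reference lengths and inverse-frequency class weights
    are computed on the training fold only; a fresh model (seeded from
    ``config.seed`` plus the fold index, so reruns are bit-reproducible) is
    trained and applied to the held-out subject, whose sequences are padded
    to the training references with tail truncation if they run longer.
    """
    folds = lopo_split(sessions)
    predictions: dict[str, Prediction] = {}
    profiles: dict[str, AttentionProfile] = {}
    labels = {s.subject_id: s.label for s in sessions}
    for fold_idx, (train, held_out) in enumerate(folds):
        refs = compute_reference_lengths(train)
        train_batch = pad_sessions(train, refs, OverflowPolicy.ERROR)
        counts = np.bincount(train_batch.label_indices(), minlength=3)
        if np.any(counts == 0):
            raise ValueError(
                f"fold {fold_idx}: class absent from the training fold"
            )
        weights = class_weights_from_counts(counts)
        model = StageAttentionClassifier(
            replace(config, seed=config.seed + fold_idx)
        )
        try:
            model.fit(train_batch, class_weights=weights)
        except FloatingPointError as exc:
            raise FloatingPointError(f"fold {fold_idx}: {exc}") from exc
        test_batch = pad_sessions(
            [held_out], refs, OverflowPolicy.TRUNCATE_TAIL
        )
        pred = model.predict(test_batch)[0]
        predictions[held_out.subject_id] = pred
        if config.use_attention:
            profiles[held_out.subject_id] = model.attention_profiles(
                test_batch
            )[0]
        if progress is not None:
            progress(fold_idx + 1, len(folds))
    ids = [s.subject_id for s in sessions]
    confusion = ConfusionMatrix3.from_predictions(
        [labels[i] for i in ids], [predictions[i].predicted_label for i in ids]
    )
    return CVResult(
        confusion=confusion,
        predictions=predictions,
        profiles=profiles,
        labels=labels,
    )
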