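"""Performance grouping, cohort statistics and prediction-table summaries.

A *prediction table* holds, per subject, the predicted label of the rest
segment and of the task segment. The summary statistics mirror the
subject-level bookkeeping of the study design:

* both-class accuracy — fraction of subjects with rest -> class_1 AND
  task -> class_2;
* class-1 / class-2 accuracy — per-condition fractions;
* overall accuracy — correct segment predictions over all 2n segments;
* error-pattern counts — "Reversed" (class_2, class_1) rows and rows where
  both segments collapsed onto one class.

Cohort completion-rate statistics use the sample (n-1) standard deviation —
deliberately different from the population (1/n) moments of the per-mode
signal features, which follow the feature definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import REST_LABEL, TASK_LABEL
from .errors import ValidationError
from .io import PERFORMANCE_THRESHOLD, SubjectMeta

__all__ = [
    "EvaluationSummary",
    "group_by_performance",
    "group_stats",
    "evaluate_prediction_table",
]


@dataclass(frozen=True)
class EvaluationSummary:
    """Subject-level accuracy statistics of one prediction table (percent)."""

    n: int
    both_class_accuracy: float
    class1_accuracy: float
    class2_accuracy: float
    overall_accuracy: float
    n_reversed: int
    n_both_as_class1: int
    n_both_as_class2: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def group_by_performance(manifest: list[SubjectMeta],
                         threshold: float = PERFORMANCE_THRESHOLD,
                         ) -> tuple[list[SubjectMeta], list[SubjectMeta]]:
    """Split a manifest into (BAD, GOOD) by completion rate, preserving order.

    A subject with X exactly at the threshold is a BAD performer.
    """
    if not manifest:
        raise ValidationError("manifest is empty")
    bad = [m for m in manifest if m.X <= threshold]
    good = [m for m in manifest if m.X > threshold]
    return bad, good


def group_stats(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation of completion rates."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 values for a sample SD")
    return float(values.mean()), float(values.std(ddof=1))


def evaluate_prediction_table(table: pd.DataFrame) -> EvaluationSummary:
    """Compute the subject-level accuracy summary of a prediction table.

    ``table`` needs columns ``subject_id``, ``pred_rest``, ``pred_task``
    with labels from {class_1, class_2}; subject ids must be unique. Row
    order does not affect any statistic.
    """
    required = {"subject_id", "pred_rest", "pred_task"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"prediction table lacks columns: {sorted(missing)}")
    if table.empty:
        raise ValidationError("prediction table is empty")
    if table["subject_id"].duplicated().any():
        raise ValidationError("prediction table has duplicate subject ids")
    labels = set(table["pred_rest"]) | set(table["pred_task"])
    unknown = labels - {REST_LABEL, TASK_LABEL}
    if unknown:
        raise ValidationError(f"unknown prediction labels: {sorted(unknown)}")

    n = len(table)
    rest_ok = table["pred_rest"].eq(REST_LABEL)
    task_ok = table["pred_task"].eq(TASK_LABEL)
    both_ok = rest_ok & task_ok
    identical = table["pred_rest"].eq(table["pred_task"])
    reversed_ = ~rest_ok & ~task_ok
    return EvaluationSummary(
        n=n,
        both_class_accuracy=float(both_ok.mean() * 100),
        class1_accuracy=float(rest_ok.mean() * 100),
        class2_accuracy=float(task_ok.mean() * 100),
        overall_accuracy=float((rest_ok.sum() + task_ok.sum()) / (2 * n) * 100),
        n_reversed=int(reversed_.sum()),
        n_both_as_class1=int((identical & table["pred_rest"].eq(REST_LABEL) & ~both_ok).sum()),
        n_both_as_class2=int((identical & table["pred_rest"].eq(TASK_LABEL) & ~both_ok).sum()),
    )
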