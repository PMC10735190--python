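"""Rest/task SVM classification and the five train/test experiment designs.

The classifier is a soft-margin SVM with a degree-4 polynomial kernel on
standardized features, K(x, z) = (x.z / d + 1)^order with d the number of
(non-degenerate) features — the common "standardized predictors +
polynomial kernel" semantics. Labels are ``class_1`` (rest) and
``class_2`` (task).

Experiment designs split *subjects*, never single segments, so both
condition vectors of a subject always land on the same side of a split:

* E1 — train on the first 20 subjects, test on the remaining 16.
* E2 — train on the first 20, evaluate all 36 (training subjects included,
  as the whole-cohort summary does).
* E3 — train on the BAD performers, test on the GOOD performers.
* E4 — train on the 10 lowest-rate GOOD performers ("Average_GOOD"), test
  on the 16 remaining GOOD performers.
* E5 — train on the first 18 subjects, evaluate all 36.

For cohorts of other sizes the counts scale proportionally (see
:func:`make_design`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import InvalidTrainingError, ValidationError
from .features import FeatureVector
from .io import SubjectMeta

__all__ = [
    "REST_LABEL",
    "TASK_LABEL",
    "LabeledSet",
    "ExperimentDesign",
    "CognitiveLoadSVC",
    "train_svm",
    "predict",
    "make_design",
    "run_experiment",
    "order_sweep",
    "baseline_comparison",
]

REST_LABEL = "class_1"
TASK_LABEL = "class_2"
_CONDITION_LABEL = {"rest": REST_LABEL, "task": TASK_LABEL}


@dataclass
class LabeledSet:
    """Feature vectors with class labels, one rest and one task per subject."""

    vectors: list[FeatureVector]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [_CONDITION_LABEL[v.condition] for v in self.vectors]
        if len(self.labels) != len(self.vectors):
            raise ValidationError("labels and vectors differ in length")
        seen: dict[str, set[str]] = {}
        for v, label in zip(self.vectors, self.labels):
            if label != _CONDITION_LABEL[v.condition]:
                raise ValidationError(
                    f"{v.subject_id}: {v.condition} vector labeled {label!r}"
                )
            conds = seen.setdefault(v.subject_id, set())
            if v.condition in conds:
                raise ValidationError(f"duplicate {v.condition} vector for {v.subject_id}")
            conds.add(v.condition)
        incomplete = [s for s, c in seen.items() if c != {"rest", "task"}]
        if incomplete:
            raise ValidationError(f"subjects missing a condition: {sorted(incomplete)}")

    @property
    def subject_ids(self) -> list[str]:
        out: list[str] = []
        for v in self.vectors:
            if v.subject_id not in out:
                out.append(v.subject_id)
        return out

    def subset(self, subject_ids) -> "LabeledSet":
        wanted = set(subject_ids)
        return LabeledSet(vectors=[v for v in self.vectors if v.subject_id in wanted])

    def matrix(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.vstack([v.values for v in self.vectors])
        y = np.asarray(self.labels)
        return X, y


@dataclass(frozen=True)
class ExperimentDesign:
    name: str
    train_subject_ids: tuple[str, ...]
    test_subject_ids: tuple[str, ...]

    @property
    def disjoint(self) -> bool:
        return not set(self.train_subject_ids) & set(self.test_subject_ids)


class CognitiveLoadSVC(ClassifierMixin, BaseEstimator):
    """Polynomial-kernel SVM on standardized features with a rest-tie rule.

    Standardization statistics come from the training set only;
    zero-variance training features are excluded from the model (and
    ignored at predict time, which equals re-inserting them as zeros).
    An exactly-zero decision function predicts ``class_1`` — ties resolve
    toward the null (rest) state.

    Parameters
    ----------
    order : polynomial kernel degree (study default 4).
    C : soft-margin penalty.
    """

    def __init__(self, order: int = 4, C: float = 1.0):
        self.order = order
        self.C = C

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise InvalidTrainingError("training set contains a single class")
        if self.classes_.size > 2:
            raise InvalidTrainingError(f"expected 2 classes, got {self.classes_.size}")
        std = X.std(axis=0)
        self.feature_mask_ = std > 0
        if not self.feature_mask_.any():
            raise InvalidTrainingError("all training features are constant")
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.where(self.feature_mask_, std, 1.0)
        Z = self._standardize(X)
        n_active = int(self.feature_mask_.sum())
        self.svc_ = SVC(kernel="poly", degree=self.order, gamma=1.0 / n_active,
                        coef0=1.0, C=self.C)
        self.svc_.fit(Z, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return ((X - self.mean_) / self.scale_)[:, self.feature_mask_]

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "svc_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fit with {self.n_features_in_}"
            )
        df = self.svc_.decision_function(self._standardize(X))
        # sklearn orients the binary decision function toward classes_[1]
        return df if np.array_equal(self.svc_.classes_, self.classes_) else -df

    def predict(self, X) -> np.ndarray:
        df = self.decision_function(X)
        # strict inequality: an exact tie falls back to the rest class
        return np.where(df > 0, self.classes_[1], self.classes_[0])


def train_svm(train: LabeledSet, order: int = 4, C: float = 1.0) -> CognitiveLoadSVC:
    """Fit the study's classifier on a labeled training set."""
    X, y = train.matrix()
    return CognitiveLoadSVC(order=order, C=C).fit(X, y)


def predict(model: CognitiveLoadSVC, vectors: list[FeatureVector]) -> np.ndarray:
    """Predict class labels for feature vectors."""
    return model.predict(np.vstack([v.values for v in vectors]))


def _scaled(count_at_36: int, n: int) -> int:
    """Scale a split size defined for the 36-subject cohort to ``n`` subjects."""
    if n == 36:
        return count_at_36
    return max(1, min(n - 1, round(count_at_36 * n / 36)))


def make_design(name: str, manifest: list[SubjectMeta]) -> ExperimentDesign:
    """Build one of the five experiment designs from a subject manifest.

    "First N subjects" means ascending subject-id order. E4 sorts the GOOD
    performers by ascending completion rate (stable in subject id on ties)
    and trains on the lower ten twenty-sixths of them.
    """
    name = name.upper()
    metas = sorted(manifest, key=lambda m: m.subject_id)
    ids = [m.subject_id for m in metas]
    n = len(ids)
    if n < 2:
        raise ValidationError("manifest must contain at least 2 subjects")
    if name in ("E1", "E2"):
        k = _scaled(20, n)
        train = ids[:k]
        test = ids[k:] if name == "E1" else ids
    elif name == "E3":
        train = [m.subject_id for m in metas if m.group == "BAD"]
        test = [m.subject_id for m in metas if m.group == "GOOD"]
        if not train or not test:
            raise ValidationError("E3 needs both BAD and GOOD performers")
    elif name == "E4":
        good = sorted((m for m in metas if m.group == "GOOD"),
                      key=lambda m: (m.X, m.subject_id))
        if len(good) < 2:
            raise ValidationError("E4 needs at least 2 GOOD performers")
        k = 10 if len(good) == 26 else max(1, min(len(good) - 1, round(10 * len(good) / 26)))
        train = [m.subject_id for m in good[:k]]
        test = [m.subject_id for m in good[k:]]
    elif name == "E5":
        k = _scaled(18, n)
        train = ids[:k]
        test = ids
    else:
        raise ValidationError(f"unknown experiment design {name!r}")
    return ExperimentDesign(name=name, train_subject_ids=tuple(train),
                            test_subject_ids=tuple(test))


def run_experiment(design: ExperimentDesign, dataset: LabeledSet,
                   manifest: list[SubjectMeta] | None = None,
                   order: int = 4, C: float = 1.0) -> pd.DataFrame:
    """Train on the design's training subjects, predict every test subject.

    Returns a prediction table with one row per test subject: columns
    ``subject_id, X, group, pred_rest, pred_task, comment``. ``X``/``group``
    are filled from ``manifest`` when given, else NaN/empty.
    """
    model = train_svm(dataset.subset(design.train_subject_ids), order=order, C=C)
    by_subject = {(v.subject_id, v.condition): v for v in dataset.vectors}
    meta = {m.subject_id: m for m in (manifest or [])}
    rows = []
    for sid in design.test_subject_ids:
        rest_v = by_subject[(sid, "rest")]
        task_v = by_subject[(sid, "task")]
        pred_rest, pred_task = predict(model, [rest_v, task_v])
        rows.append({
            "subject_id": sid,
            "X": meta[sid].X if sid in meta else np.nan,
            "group": meta[sid].group if sid in meta else "",
            "pred_rest": pred_rest,
            "pred_task": pred_task,
            "comment": _comment(pred_rest, pred_task),
        })
    return pd.DataFrame(rows, columns=["subject_id", "X", "group",
                                       "pred_rest", "pred_task", "comment"])


def _comment(pred_rest: str, pred_task: str) -> str:
    if pred_rest == REST_LABEL and pred_task == TASK_LABEL:
        return "correct"
    if pred_rest == TASK_LABEL and pred_task == REST_LABEL:
        return "Reversed"
    return "Both_as_class_1" if pred_rest == REST_LABEL else "Both_as_class_2"


def order_sweep(dataset: LabeledSet, design: ExperimentDesign,
                orders: list[int], manifest: list[SubjectMeta] | None = None,
                C: float = 1.0) -> pd.DataFrame:
    """Overall accuracy of the experiment for each polynomial order."""
    from .evaluate import evaluate_prediction_table

    if not orders:
        raise ValidationError("orders must be non-empty")
    rows = []
    for order in orders:
        table = run_experiment(design, dataset, manifest=manifest, order=order, C=C)
        summary = evaluate_prediction_table(table)
        rows.append({"order": order, "overall_accuracy": summary.overall_accuracy,
                     "both_class_accuracy": summary.both_class_accuracy})
    return pd.DataFrame(rows)


def baseline_comparison(dataset: LabeledSet, design: ExperimentDesign,
                        order: int = 4, C: float = 1.0) -> pd.DataFrame:
    """Accuracy of the SVM against four standard baselines on one design.

    Baselines (library defaults, standardized inputs like the SVM): linear
    discriminant analysis, k-nearest neighbours, decision tree, Gaussian
    naive Bayes. Returns one row per classifier with both-class and
    overall accuracy in percent.
    """
    from .evaluate import evaluate_prediction_table

    train = dataset.subset(design.train_subject_ids)
    X_train, y_train = train.matrix()
    std = X_train.std(axis=0)
    mask = std > 0
    mu, sc = X_train.mean(axis=0), np.where(mask, std, 1.0)

    def standardized(X):
        return ((X - mu) / sc)[:, mask]

    classifiers = {
        "LDA": LinearDiscriminantAnalysis(),
        "SVM": CognitiveLoadSVC(order=order, C=C),
        "kNN": KNeighborsClassifier(),
        "Decision tree": DecisionTreeClassifier(random_state=0),
        "Naive Bayes": GaussianNB(),
    }
    by_subject = {(v.subject_id, v.condition): v for v in dataset.vectors}
    rows = []
    for name, clf in classifiers.items():
        if isinstance(clf, CognitiveLoadSVC):
            clf.fit(X_train, y_train)
            model_predict = clf.predict
        else:
            clf.fit(standardized(X_train), y_train)
            model_predict = lambda X: clf.predict(standardized(X))  # noqa: E731
        table_rows = []
        for sid in design.test_subject_ids:
            vecs = np.vstack([by_subject[(sid, "rest")].values,
                              by_subject[(sid, "task")].values])
            pred_rest, pred_task = model_predict(vecs)
            table_rows.append({"subject_id": sid, "X": np.nan,
                               "pred_rest": pred_rest, "pred_task": pred_task})
        summary = evaluate_prediction_table(pd.DataFrame(table_rows))
        rows.append({"classifier": name,
                     "both_class_accuracy": summary.both_class_accuracy,
                     "overall_accuracy": summary.overall_accuracy})
    return pd.DataFrame(rows)
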