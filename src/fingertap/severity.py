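"""Severity labels, classifiers, leave-one-subject-out evaluation and metrics.

Clinical 0-4 item scores are merged into three ordered severity groups —
Mild (0-1), Moderate (2), Severe (3-4) — to mitigate class imbalance.  Two
classification strategies are supported:

* multi-class — one classifier over the three groups;
* ordinal — Frank–Hall decomposition into K-1 = 2 cumulative binary tasks
  (P(y > Mild) and P(y > Moderate)) whose probabilities are differenced into
  class probabilities.

Evaluation is leave-one-subject-out (LOSO): all recordings of one subject
form the test fold, so no subject ever contributes to its own training data.
Hyperparameters may be tuned inside each outer fold by a bounded random
search over grouped, label-stratified 5-fold splits of the training
subjects.  Metric conventions: balanced accuracy is the mean per-class
recall over classes present in the truth; precision of a never-predicted
class is 0; F1 is the standard harmonic mean 2PR/(P+R).  All metrics are
reported as percentages.
"""

from __future__ import annotations

import enum
import json
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold, LeaveOneGroupOut, StratifiedGroupKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ValidationError

logger = logging.getLogger(__name__)


class SeverityLabel(enum.IntEnum):
    """Ordered severity groups; the int order is the clinical order."""

    MILD = 0
    MODERATE = 1
    SEVERE = 2

    def __str__(self) -> str:  # "Mild" etc.
        return self.name.capitalize()


LABELS = [SeverityLabel.MILD, SeverityLabel.MODERATE, SeverityLabel.SEVERE]
LABEL_NAMES = [str(lbl) for lbl in LABELS]


def merge_scores(score: int) -> SeverityLabel:
    """Merge a 0-4 item score into its severity group."""
    if score not in (0, 1, 2, 3, 4):
        raise ValidationError(f"severity score must be in 0..4, got {score!r}")
    if score <= 1:
        return SeverityLabel.MILD
    if score == 2:
        return SeverityLabel.MODERATE
    return SeverityLabel.SEVERE


def majority_vote(ratings) -> int:
    """Most frequent rating; ties break toward the lower (less severe) score."""
    ratings = list(ratings)
    if not ratings:
        raise ValidationError("majority_vote needs >= 1 rating")
    for r in ratings:
        if r not in (0, 1, 2, 3, 4):
            raise ValidationError(f"rating must be in 0..4, got {r!r}")
    counts = Counter(ratings)
    best = max(counts.values())
    return min(r for r, c in counts.items() if c == best)


@dataclass
class SeverityDataset:
    """Feature matrix with severity labels and subject grouping."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray
    recording_ids: np.ndarray | None = None
    feature_names: list[str] | None = None
    raw_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.recording_ids is not None:
            self.recording_ids = np.asarray(self.recording_ids)
        if len(self.X) != len(self.y) or len(self.y) != len(self.subject_ids):
            raise ValidationError("X, y and subject_ids must have equal length")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.subject_ids))


@dataclass
class MetricsReport:
    """The four headline metrics (percentages) plus per-class detail."""

    accuracy: float
    balanced_accuracy: float
    macro_precision: float
    macro_f1: float
    per_class: dict
    confusion: np.ndarray
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "per_class": self.per_class,
            "confusion": self.confusion.tolist(),
            "n_samples": self.n_samples,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [
            f"n_samples: {self.n_samples}",
            f"accuracy: {self.accuracy:.2f}",
            f"balanced_accuracy: {self.balanced_accuracy:.2f}",
            f"macro_precision: {self.macro_precision:.2f}",
            f"macro_f1: {self.macro_f1:.2f}",
        ]
        return "\n".join(lines)


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """Accuracy, balanced accuracy, macro precision and macro F1 (in %).

    Macro averages run over the classes present in ``y_true``.  A class the
    model never predicts has precision 0; a class with P + R = 0 has F1 = 0.
    The confusion matrix is always the full 3x3 severity table (rows: truth,
    columns: prediction).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ValidationError("y_true and y_pred length mismatch")
    if len(y_true) == 0:
        raise ValidationError("compute_metrics needs >= 1 sample")

    n_labels = len(LABELS)
    confusion = np.zeros((n_labels, n_labels), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[t, p] += 1

    accuracy = 100.0 * np.mean(y_true == y_pred)
    present = [int(c) for c in np.unique(y_true)]
    per_class = {}
    recalls, precisions, f1s = [], [], []
    for c in range(n_labels):
        tp = confusion[c, c]
        support = confusion[c].sum()
        predicted = confusion[:, c].sum()
        recall = tp / support if support else 0.0
        precision = tp / predicted if predicted else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
        per_class[LABEL_NAMES[c]] = {
            "precision": 100.0 * precision,
            "recall": 100.0 * recall,
            "f1": 100.0 * f1,
            "support": int(support),
        }
        if c in present:
            recalls.append(recall)
            precisions.append(precision)
            f1s.append(f1)

    return MetricsReport(
        accuracy=float(accuracy),
        balanced_accuracy=float(100.0 * np.mean(recalls)),
        macro_precision=float(100.0 * np.mean(precisions)),
        macro_f1=float(100.0 * np.mean(f1s)),
        per_class=per_class,
        confusion=confusion,
        n_samples=len(y_true),
    )


# --------------------------------------------------------------------------
# base learners

#: bounded random-search spaces per learner (values sampled uniformly)
SEARCH_SPACES = {
    "logistic": {"logisticregression__C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "lightgbm": {
        "n_estimators": [50, 100, 200],
        "num_leaves": [7, 15, 31],
        "learning_rate": [0.05, 0.1],
        "min_child_samples": [5, 10, 20],
    },
    "random_forest": {
        "n_estimators": [100, 200],
        "max_depth": [None, 4, 8],
        "min_samples_leaf": [1, 3, 5],
    },
    "majority": {},
}


def make_base_learner(name: str, seed: int = 0):
    """Instantiate one of the supported probabilistic classifiers."""
    if name == "logistic":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, random_state=seed),
        )
    if name == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            random_state=seed, verbose=-1, n_estimators=100, num_leaves=15
        )
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "majority":
        return DummyClassifier(strategy="most_frequent")
    raise ValidationError(f"unknown base learner {name!r}")


def _predict_proba(clf, X) -> np.ndarray:
    # lightgbm's sklearn wrapper warns about feature names when fitted and
    # queried with plain arrays; the warning is spurious here
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names"
        )
        return clf.predict_proba(X)


def _proba_over_labels(clf, X) -> np.ndarray:
    """predict_proba expanded to the full 3-class layout."""
    probs = _predict_proba(clf, X)
    out = np.zeros((len(X), len(LABELS)))
    for j, c in enumerate(clf.classes_):
        out[:, int(c)] = probs[:, j]
    return out


class _ConstantBinary:
    """Degenerate stand-in when a cumulative task sees a single class."""

    def __init__(self, value: float):
        self.value = value

    def predict_proba_positive(self, X) -> np.ndarray:
        return np.full(len(X), self.value)


def _fit_binary(learner, X, y01, seed: int):
    if len(np.unique(y01)) < 2:
        logger.warning("cumulative binary task degenerate (single class)")
        return _ConstantBinary(float(y01[0]))
    clf = clone(learner)
    clf.fit(X, y01)
    return clf


def _positive_proba(clf, X) -> np.ndarray:
    if isinstance(clf, _ConstantBinary):
        return clf.predict_proba_positive(X)
    probs = _predict_proba(clf, X)
    pos_col = list(clf.classes_).index(1)
    return probs[:, pos_col]


def frank_hall_probabilities(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Class probabilities from cumulative probabilities.

    q1 = P(y > Mild), q2 = P(y > Moderate).  The raw triplet
    (1-q1, q1-q2, q2) can have a negative middle when the two cumulative
    models disagree; it is clipped to 0 and the triplet renormalised.
    """
    probs = np.column_stack([1.0 - q1, q1 - q2, q2])
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=1, keepdims=True)
    return probs


def ordinal_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    base_learner,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Frank–Hall ordinal classification over the three severity groups.

    Two binary probabilistic classifiers are trained on the cumulative tasks
    y > Mild and y > Moderate; their probabilities are differenced, clipped
    and renormalised.  Prediction is the argmax, ties resolved toward the
    less severe label.
    """
    y_train = np.asarray(y_train, dtype=int)
    if isinstance(base_learner, str):
        base_learner = make_base_learner(base_learner, seed)
    clf1 = _fit_binary(base_learner, X_train, (y_train > 0).astype(int), seed)
    clf2 = _fit_binary(base_learner, X_train, (y_train > 1).astype(int), seed)
    q1 = _positive_proba(clf1, X_test)
    q2 = _positive_proba(clf2, X_test)
    probs = frank_hall_probabilities(q1, q2)
    preds = probs.argmax(axis=1)  # argmax takes the first (least severe) on ties
    return preds, probs


def multiclass_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    base_learner,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Plain multi-class fit/predict with full 3-class probability layout."""
    if isinstance(base_learner, str):
        base_learner = make_base_learner(base_learner, seed)
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        # single-class training fold (e.g. two-subject LOSO): a prediction
        # must still be produced
        logger.warning("single-class training fold; emitting constant prediction")
        probs = np.zeros((len(X_test), len(LABELS)))
        probs[:, int(y_train[0])] = 1.0
        return probs.argmax(axis=1), probs
    clf = clone(base_learner)
    clf.fit(X_train, y_train)
    probs = _proba_over_labels(clf, X_test)
    preds = probs.argmax(axis=1)
    return preds, probs


# --------------------------------------------------------------------------
# nested LOSO evaluation


def _sample_params(space: dict, rng: np.random.Generator) -> dict:
    return {k: v[rng.integers(len(v))] for k, v in space.items()}


def _inner_cv_score(
    learner,
    params: dict,
    X,
    y,
    groups,
    mode: str,
    inner_folds: int,
    seed: int,
) -> float:
    n_groups = len(np.unique(groups))
    n_splits = max(2, min(inner_folds, n_groups))
    try:
        splitter = StratifiedGroupKFold(
            n_splits=n_splits, shuffle=True, random_state=seed
        )
        splits = list(splitter.split(X, y, groups))
    except ValueError:
        splits = list(GroupKFold(n_splits=n_splits).split(X, y, groups))
    scores = []
    for tr, va in splits:
        if len(np.unique(y[tr])) < 2:
            continue
        est = clone(learner).set_params(**params)
        if mode == "ordinal":
            preds, _ = ordinal_fit_predict(X[tr], y[tr], X[va], est, seed)
        else:
            preds, _ = multiclass_fit_predict(X[tr], y[tr], X[va], est, seed)
        scores.append(compute_metrics(y[va], preds).balanced_accuracy)
    return float(np.mean(scores)) if scores else -np.inf


def loso_evaluate(
    data: SeverityDataset,
    model: str = "lightgbm",
    mode: str = "multiclass",
    inner_folds: int = 5,
    tuning_budget: int = 0,
    seed: int = 0,
) -> tuple[MetricsReport, pd.DataFrame]:
    """Leave-one-subject-out evaluation with optional nested tuning.

    The outer loop holds out every recording of one subject.  When
    ``tuning_budget`` > 0, that many hyperparameter draws from the learner's
    search space are scored by grouped, label-stratified ``inner_folds``-fold
    CV on the training subjects, and the best draw refits on the full outer
    training split.  All pooled outer-fold predictions feed one
    :class:`MetricsReport`.  Fully reproducible given ``seed``.
    """
    if mode not in ("multiclass", "ordinal"):
        raise ValidationError("mode must be 'multiclass' or 'ordinal'")
    if data.n_subjects < 2:
        raise ValidationError("LOSO needs >= 2 subjects")
    if len(np.unique(data.y)) < 2:
        raise ValidationError("LOSO needs >= 2 classes overall")

    rng = np.random.default_rng(seed)
    if isinstance(model, str):
        learner = make_base_learner(model, seed)
        space = SEARCH_SPACES.get(model, {})
    else:  # any sklearn-compatible probabilistic classifier
        learner = model
        space = {}

    records = []
    logo = LeaveOneGroupOut()
    for fold, (tr, te) in enumerate(
        logo.split(data.X, data.y, groups=data.subject_ids)
    ):
        assert not set(data.subject_ids[te]) & set(data.subject_ids[tr])
        X_tr, y_tr = data.X[tr], data.y[tr]
        X_te = data.X[te]

        params: dict = {}
        if tuning_budget > 0 and space:
            candidates = [_sample_params(space, rng) for _ in range(tuning_budget)]
            scores = [
                _inner_cv_score(
                    learner,
                    p,
                    X_tr,
                    y_tr,
                    data.subject_ids[tr],
                    mode,
                    inner_folds,
                    seed,
                )
                for p in candidates
            ]
            params = candidates[int(np.argmax(scores))]

        est = clone(learner).set_params(**params) if params else clone(learner)
        if mode == "ordinal":
            preds, probs = ordinal_fit_predict(X_tr, y_tr, X_te, est, seed)
        else:
            preds, probs = multiclass_fit_predict(X_tr, y_tr, X_te, est, seed)

        for i, idx in enumerate(te):
            records.append(
                {
                    "recording_id": (
                        data.recording_ids[idx]
                        if data.recording_ids is not None
                        else str(idx)
                    ),
                    "subject_id": data.subject_ids[idx],
                    "true": int(data.y[idx]),
                    "predicted": int(preds[i]),
                    "p_mild": probs[i, 0],
                    "p_moderate": probs[i, 1],
                    "p_severe": probs[i, 2],
                }
            )

    pred_df = pd.DataFrame.from_records(records)
    report = compute_metrics(pred_df["true"], pred_df["predicted"])
    return report, pred_df
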