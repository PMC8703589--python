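"""Per-sample exercise/pose prediction with an SVM, evaluated by LOSO-CV.

Each frame is a 60-dimensional feature vector: for every node in the
canonical order, the 3 accelerometer axes (gravity included) followed by
the 3 gyroscope axes.  The classifier predicts one of the per-sample
labels ``<exercise>_POSE`` / ``<exercise>_REP`` / ``NEGATIVE_NONE`` so
the exercise can be identified from its starting pose, before the first
repetition begins.

Defaults (kernel, regularization, standardization) are this package's
choices: RBF kernel, C = 1, gamma = 1 / (n_features * var) and per-feature
z-scoring fit on the training folds only.  Multiclass decisions are
one-vs-one by vote.  Per-sample classification (denoise window 1) is the
default; accuracy was best without smoothing in the source study.

Macro-averaged precision/recall/F1 are computed from the pooled confusion
matrix over all held-out predictions: per-class scores first (classes
never predicted and never present contribute zeros), then the unweighted
mean over classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import moving_average
from .types import Frame, NODE_NAMES, Recording, SchemaError

__all__ = [
    "ClassifierConfig",
    "ClassifierModel",
    "CVResult",
    "extract_features",
    "feature_matrix",
    "train_classifier",
    "predict",
    "loso_cv",
    "metrics_from_confusion",
]

N_FEATURES = len(NODE_NAMES) * 6


def feature_index(node: str, sensor: str, axis: int) -> int:
    """Index of (node, 'acc'|'gyr', axis) in the canonical 60-vector."""
    base = NODE_NAMES.index(node) * 6
    return base + (0 if sensor == "acc" else 3) + axis


@dataclass
class ClassifierConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str = "scale"
    denoise_window: int = 1
    frame_stride: int = 1  # keep every k-th frame (computational thinning)

    def __post_init__(self) -> None:
        if self.denoise_window < 1:
            raise ValueError("denoise_window must be >= 1")
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")


@dataclass
class ClassifierModel:
    pipeline: Pipeline
    labels: List[str]
    config: ClassifierConfig


def extract_features(frame: Frame) -> np.ndarray:
    """Deterministic 60-vector: per node, accel xyz then gyro xyz."""
    missing = set(NODE_NAMES) - set(frame.nodes)
    if missing:
        raise SchemaError(f"frame missing nodes {sorted(missing)}")
    out = np.empty(N_FEATURES)
    for i, n in enumerate(NODE_NAMES):
        out[6 * i : 6 * i + 3] = frame.nodes[n].accel
        out[6 * i + 3 : 6 * i + 6] = frame.nodes[n].gyro
    return out


def feature_matrix(rec: Recording, denoise_window: int = 1) -> np.ndarray:
    """(n_frames, 60) feature matrix with optional causal denoising
    applied per node stream before assembly."""
    cols = []
    for n in NODE_NAMES:
        acc = rec.accel(n)
        gyr = rec.gyro(n)
        if denoise_window > 1:
            acc = moving_average(acc, denoise_window)
            gyr = moving_average(gyr, denoise_window)
        cols.append(acc)
        cols.append(gyr)
    return np.hstack(cols)


def _pool(
    recordings: Sequence[Recording], config: ClassifierConfig
) -> Tuple[np.ndarray, np.ndarray]:
    Xs, ys = [], []
    for rec in recordings:
        if rec.labels is None:
            raise SchemaError("every recording must be fully labeled")
        X = feature_matrix(rec, config.denoise_window)
        y = np.asarray(rec.labels)
        sl = slice(None, None, config.frame_stride)
        Xs.append(X[sl])
        ys.append(y[sl])
    return np.vstack(Xs), np.concatenate(ys)


def train_classifier(
    recordings: Sequence[Recording],
    config: Optional[ClassifierConfig] = None,
) -> ClassifierModel:
    """Fit the standardizer + SVM on pooled labeled frames."""
    config = config or ClassifierConfig()
    X, y = _pool(recordings, config)
    labels = sorted(set(y))
    if len(labels) < 2:
        raise ValueError("training data must contain at least 2 distinct labels")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel=config.kernel,
                    C=config.C,
                    gamma=config.gamma,
                    decision_function_shape="ovo",
                ),
            ),
        ]
    )
    pipe.fit(X, y)
    return ClassifierModel(pipeline=pipe, labels=labels, config=config)


def predict(model: ClassifierModel, rec: Recording) -> np.ndarray:
    """Per-frame label predictions for one recording."""
    X = feature_matrix(rec, model.config.denoise_window)
    return model.pipeline.predict(X)


def metrics_from_confusion(cm: np.ndarray) -> Dict[str, float]:
    """Accuracy (%) and macro precision/recall/F1 from a count matrix
    (rows = true class, columns = predicted class)."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(cm)
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / col, 0.0)
        recall = np.where(row > 0, diag / row, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / pr, 0.0)
    return {
        "accuracy": 100.0 * diag.sum() / total,
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
    }


@dataclass
class CVResult:
    accuracy: float  # percent
    macro_f1: float
    macro_precision: float
    macro_recall: float
    labels: List[str]
    confusion: np.ndarray  # pooled counts, rows = true
    per_subject: List[dict] = field(default_factory=list)
    y_true: np.ndarray = field(default_factory=lambda: np.array([]))
    y_pred: np.ndarray = field(default_factory=lambda: np.array([]))

    def validate(self) -> None:
        if not 0 <= self.accuracy <= 100:
            raise ValueError("accuracy must lie in [0, 100]")
        for m in (self.macro_f1, self.macro_precision, self.macro_recall):
            if not 0 <= m <= 1:
                raise ValueError("macro metrics must lie in [0, 1]")


def _confusion(y_true, y_pred, labels: List[str]) -> np.ndarray:
    index = {l: i for i, l in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def loso_cv(
    recordings: Sequence[Recording],
    config: Optional[ClassifierConfig] = None,
) -> CVResult:
    """Leave-one-subject-out cross-validation over labeled recordings.

    For each subject a model is trained on all remaining subjects and
    tested on that subject's frames; metrics are computed on the pooled
    held-out predictions.  The result is invariant to the order in which
    recordings are supplied.
    """
    config = config or ClassifierConfig()
    by_subject: Dict[str, List[Recording]] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    subjects = sorted(by_subject)
    if len(subjects) < 2:
        raise ValueError("LOSO-CV needs at least 2 subjects")
    for s, recs in by_subject.items():
        if sum(r.n_frames for r in recs) == 0:
            raise ValueError(f"subject {s!r} has zero frames")

    all_labels = sorted(
        {l for rec in recordings if rec.labels for l in rec.labels}
    )
    y_true_all, y_pred_all = [], []
    per_subject = []
    for s in subjects:
        train = [r for t in subjects if t != s for r in by_subject[t]]
        model = train_classifier(train, config)
        Xte, yte = _pool(by_subject[s], config)
        yp = model.pipeline.predict(Xte)
        y_true_all.append(yte)
        y_pred_all.append(yp)
        sub_cm = _confusion(yte, yp, all_labels)
        per_subject.append(
            {"subject": s, "confusion": sub_cm, **metrics_from_confusion(sub_cm)}
        )
    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    cm = _confusion(y_true, y_pred, all_labels)
    m = metrics_from_confusion(cm)
    result = CVResult(
        accuracy=m["accuracy"],
        macro_f1=m["macro_f1"],
        macro_precision=m["macro_precision"],
        macro_recall=m["macro_recall"],
        labels=all_labels,
        confusion=cm,
        per_subject=per_subject,
        y_true=y_true,
        y_pred=y_pred,
    )
    result.validate()
    return result
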