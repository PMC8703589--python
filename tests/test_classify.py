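"""Feature extraction, SVM training and LOSO cross-validation."""

import numpy as np
import pytest
from sklearn.metrics import f1_score, precision_score, recall_score

from repcoach import (
    Frame,
    NODE_NAMES,
    SensorNodeSample,
    extract_features,
    generate_dataset,
    loso_cv,
    train_classifier,
)
from repcoach.classify import (
    ClassifierConfig,
    feature_index,
    feature_matrix,
    metrics_from_confusion,
    predict,
)
from repcoach.types import Recording, SchemaError

SUBJECTS = [f"S{i:02d}" for i in range(1, 6)]
FAST = ClassifierConfig(frame_stride=3)


def make_frame(fill=0.0, overrides=()):
    nodes = {
        n: SensorNodeSample(accel=[fill] * 3, gyro=[fill] * 3) for n in NODE_NAMES
    }
    for (node, sensor, axis), value in overrides:
        vec = nodes[node].accel if sensor == "acc" else nodes[node].gyro
        vec[axis] = value
    return Frame(t_ms=0, nodes=nodes)


def test_zero_sensors_give_zero_vector():
    np.testing.assert_array_equal(extract_features(make_frame()), np.zeros(60))


def test_feature_ordering_single_nonzero():
    f = make_frame(overrides=[(("torso", "acc", 1), 9.81)])
    v = extract_features(f)
    idx = feature_index("torso", "acc", 1)
    assert v[idx] == 9.81
    assert np.count_nonzero(v) == 1


def test_features_match_direct_field_reads():
    rec = generate_dataset(["squat"], SUBJECTS[:1], n_reps=1, seed=2)[0]
    frame = rec.frames[123]
    v = extract_features(frame)
    expected = np.concatenate(
        [np.concatenate([frame.nodes[n].accel, frame.nodes[n].gyro]) for n in NODE_NAMES]
    )
    np.testing.assert_array_equal(v, expected)
    np.testing.assert_array_equal(feature_matrix(rec)[123], expected)


def test_missing_node_is_error():
    f = make_frame()
    del f.nodes["hips"]
    with pytest.raises(SchemaError, match="hips"):
        extract_features(f)


def _two_class_recordings():
    """Two trivially separable classes for two subjects."""
    recs = []
    for s, offset in (("A", 0.0), ("B", 0.3)):
        frames, labels = [], []
        for i in range(40):
            fill = offset + (5.0 if i % 2 else 0.0)
            frames.append(
                Frame(
                    t_ms=i * 20,
                    nodes={
                        n: SensorNodeSample(accel=[fill] * 3, gyro=[fill] * 3)
                        for n in NODE_NAMES
                    },
                )
            )
            labels.append("squat_POSE" if i % 2 else "NEGATIVE_NONE")
        recs.append(Recording(frames=frames, subject_id=s, labels=labels))
    return recs


def test_separable_classes_perfect_training_accuracy():
    recs = _two_class_recordings()
    model = train_classifier(recs)
    preds = predict(model, recs[0])
    assert list(preds) == recs[0].labels
    assert set(preds) <= set(model.labels)  # closed world


def test_single_class_rejected():
    recs = _two_class_recordings()
    for r in recs:
        r.labels = ["NEGATIVE_NONE"] * r.n_frames
    with pytest.raises(ValueError, match="2 distinct"):
        train_classifier(recs)


def test_loso_two_identical_subjects_perfect():
    recs = _two_class_recordings()
    recs[1] = Recording(
        frames=recs[0].frames, subject_id="B", labels=recs[0].labels
    )
    cv = loso_cv(recs)
    assert cv.accuracy == 100.0
    assert cv.macro_f1 == 1.0


def test_loso_subject_order_invariance():
    recs = generate_dataset(["squat", "pushup"], SUBJECTS[:3], n_reps=1, seed=8)
    a = loso_cv(recs, FAST)
    b = loso_cv(list(reversed(recs)), FAST)
    assert a.accuracy == b.accuracy
    np.testing.assert_array_equal(a.confusion, b.confusion)


def test_loso_run_is_reproducible():
    recs = generate_dataset(["squat"], SUBJECTS[:3], n_reps=1, seed=9)
    a = loso_cv(recs, FAST)
    b = loso_cv(recs, FAST)
    assert round(a.accuracy, 10) == round(b.accuracy, 10)


def test_loso_requires_two_subjects():
    recs = generate_dataset(["squat"], SUBJECTS[:1], n_reps=1, seed=1)
    with pytest.raises(ValueError, match="2 subjects"):
        loso_cv(recs)


def test_all_seven_labels_predicted_on_dataset():
    recs = generate_dataset(["squat", "lunge", "pushup"], SUBJECTS[:3],
                            n_reps=1, seed=6)
    cv = loso_cv(recs, FAST)
    assert len(cv.labels) == 7
    predicted = set(cv.y_pred)
    assert predicted == set(cv.labels)


def test_confusion_conservation_and_metric_oracle():
    recs = generate_dataset(["squat", "pushup"], SUBJECTS[:3], n_reps=1, seed=13)
    cv = loso_cv(recs, FAST)
    assert cv.confusion.sum() == len(cv.y_true)
    np.testing.assert_array_equal(
        cv.confusion.sum(axis=1),
        [np.sum(cv.y_true == l) for l in cv.labels],
    )
    # independent recomputation from the raw held-out predictions
    assert cv.accuracy == pytest.approx(
        100.0 * np.mean(cv.y_true == cv.y_pred), abs=1e-12
    )
    assert cv.macro_f1 == pytest.approx(
        f1_score(cv.y_true, cv.y_pred, labels=cv.labels, average="macro"), abs=1e-12
    )
    assert cv.macro_precision == pytest.approx(
        precision_score(cv.y_true, cv.y_pred, labels=cv.labels,
                        average="macro", zero_division=0), abs=1e-12
    )
    assert cv.macro_recall == pytest.approx(
        recall_score(cv.y_true, cv.y_pred, labels=cv.labels,
                     average="macro", zero_division=0), abs=1e-12
    )


def test_metrics_from_confusion_closed_form():
    cm = np.array([[8, 2], [4, 6]])
    m = metrics_from_confusion(cm)
    assert m["accuracy"] == pytest.approx(70.0)
    assert m["macro_recall"] == pytest.approx((0.8 + 0.6) / 2)
    p0, p1 = 8 / 12, 6 / 8
    f0 = 2 * p0 * 0.8 / (p0 + 0.8)
    f1 = 2 * p1 * 0.6 / (p1 + 0.6)
    assert m["macro_f1"] == pytest.approx((f0 + f1) / 2)
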