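"""Generator schedule, determinism, label coherence and error injection."""

import numpy as np
import pytest

from repcoach import (
    ErrorSpec,
    NODE_NAMES,
    generate_recording,
    inject_error,
    recordings_equal,
)
from repcoach.segment import is_moving, is_stationary
from repcoach.synthetic import canonical_error_pattern, get_template


def test_frame_count_matches_protocol_schedule():
    # 2 s lead-in + 4 reps x 4 s + 3 breaks x 2 s + 2 s lead-out at 50 Hz
    rec = generate_recording("squat", n_reps=4, break_s=2, seed=0)
    assert rec.n_frames == 50 * (2 + 4 * 4 + 3 * 2 + 2) == 1300
    assert rec.rep_boundaries == [(100, 300), (400, 600), (700, 900), (1000, 1200)]


def test_sampling_period_is_20ms():
    rec = generate_recording("pushup", n_reps=1, break_s=1, seed=3)
    assert set(np.diff(rec.times_ms())) == {20}


def test_seeded_determinism():
    a = generate_recording("lunge", n_reps=3, break_s=1, subject_id="S05", seed=42)
    b = generate_recording("lunge", n_reps=3, break_s=1, subject_id="S05", seed=42)
    assert recordings_equal(a, b, rtol=0)


def test_noise_free_reps_are_identical():
    rec = generate_recording(
        "squat", n_reps=3, break_s=2, subject_noise=False, frame_noise_sd=0.0, seed=0
    )
    (a0, b0), (a1, b1), (a2, b2) = rec.rep_boundaries
    for j in ("pelvis", "knee_r", "wrist_l"):
        traj = rec.joint(j)
        np.testing.assert_array_equal(traj[a0:b0], traj[a1:b1])
        np.testing.assert_array_equal(traj[a0:b0], traj[a2:b2])


def test_label_consistency_with_boundaries():
    rec = generate_recording("squat", n_reps=4, break_s=1, seed=7)
    in_rep = np.zeros(rec.n_frames, dtype=bool)
    for a, b in rec.rep_boundaries:
        in_rep[a:b] = True
    labels = np.asarray(rec.labels)
    assert set(labels[in_rep]) == {"squat_REP"}
    assert "squat_REP" not in set(labels[~in_rep])
    # holds right before the first rep are POSE
    assert labels[rec.rep_boundaries[0][0] - 1] == "squat_POSE"
    assert labels[0] == "NEGATIVE_NONE" and labels[-1] == "NEGATIVE_NONE"


@pytest.mark.parametrize("exercise", ["squat", "lunge", "pushup"])
def test_gyro_label_coherence(exercise):
    """Holds stay below the stationarity threshold; every node crosses the
    moving threshold at least once per repetition."""
    rec = generate_recording(exercise, n_reps=2, break_s=2, seed=4)
    labels = np.asarray(rec.labels)
    hold = labels != f"{exercise}_REP"
    for node in NODE_NAMES:
        g = rec.gyro(node)
        assert all(is_stationary(v, 8.0) for v in g[hold])
        for a, b in rec.rep_boundaries:
            assert any(is_moving(v, 8.0) for v in g[a:b])


def test_unknown_template_rejected():
    with pytest.raises(ValueError, match="unknown exercise"):
        generate_recording("burpee", seed=0)
    with pytest.raises(ValueError):
        get_template("deadlift")


def test_template_waveform_is_cyclic():
    t = get_template("squat")
    rec = generate_recording(
        t, n_reps=1, break_s=1, subject_noise=False, frame_noise_sd=0.0, seed=0
    )
    a, b = rec.rep_boundaries[0]
    for j, pose in t.pose_joints.items():
        traj = rec.joint(j)
        np.testing.assert_allclose(traj[a], pose, atol=1e-9)
        np.testing.assert_allclose(traj[b], pose, atol=1e-9)  # back at the pose


# --- error injection ------------------------------------------------------


def test_zero_severity_is_identity(squat_model, squat_probe):
    out = inject_error(squat_probe, ErrorSpec("I", 0.0), squat_model)
    assert recordings_equal(squat_probe, out, rtol=0)


def test_type_iii_raises_movement_trough(squat_model, squat_probe):
    bad = inject_error(squat_probe, ErrorSpec("III", 3.0), squat_model)
    for a, b in squat_probe.rep_boundaries:
        clean_min = squat_probe.joint("hip_r")[a:b, 1].min()
        assert bad.joint("hip_r")[a:b, 1].min() > clean_min
    # knee height untouched: knee is not a moving joint in y
    pattern = canonical_error_pattern("III", "squat", squat_model)
    assert "knee_r" not in pattern and "ankle_l" not in pattern
    np.testing.assert_array_equal(
        bad.joint("knee_r"), squat_probe.joint("knee_r")
    )


def test_type_i_shifts_upper_spine_forward(squat_model, squat_probe):
    bad = inject_error(squat_probe, ErrorSpec("I", 3.0), squat_model)
    a, b = squat_probe.rep_boundaries[0]
    assert (
        bad.joint("upper_spine")[a:b, 2].mean()
        > squat_probe.joint("upper_spine")[a:b, 2].mean()
    )
    # labels and boundaries unchanged
    assert bad.labels == squat_probe.labels
    assert bad.rep_boundaries == squat_probe.rep_boundaries


def test_injection_input_validation(squat_model, squat_probe):
    with pytest.raises(ValueError):
        ErrorSpec("I", -1.0)
    stripped = generate_recording("squat", n_reps=1, seed=0)
    stripped.rep_boundaries = None
    with pytest.raises(ValueError, match="boundaries"):
        inject_error(stripped, ErrorSpec("I", 2.0), squat_model)
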