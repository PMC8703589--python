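"""Movement-model learning and the deviation-band error detector."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from repcoach import (
    DetectorConfig,
    MovementModel,
    TrainingConfig,
    assess_rep,
    build_model,
    detect_error,
    events_from_boundaries,
    generate_recording,
    map_index,
    resample_rep,
    split_reps,
)
from repcoach.types import Frame, NODE_NAMES, Recording, SchemaError, SensorNodeSample


def const_rep(value, length=20, joint="pelvis", subject="E"):
    frames = [
        Frame(
            t_ms=i * 20,
            nodes={
                n: SensorNodeSample(accel=[0, 9.81, 0], gyro=[0, 0, 0])
                for n in NODE_NAMES
            },
            joints={joint: [value] * 3},
        )
        for i in range(length)
    ]
    return Recording(frames=frames, subject_id=subject, exercise="squat")


# --- resampling -----------------------------------------------------------


def test_resample_identity_grid():
    traj = np.random.default_rng(0).normal(size=(7, 3))
    out = resample_rep(traj, 7)
    np.testing.assert_allclose(out, traj.T)


def test_resample_constant():
    out = resample_rep(np.ones((5, 3)) * 2.5, 11)
    np.testing.assert_allclose(out, 2.5)


def test_resample_linear_ramp_closed_form():
    ramp = np.linspace(0, 1, 4)[:, None] * np.ones(3)
    out = resample_rep(ramp, 7)
    np.testing.assert_allclose(out, np.tile(np.arange(7) / 6, (3, 1)))


def test_resample_too_short_rejected():
    with pytest.raises(ValueError):
        resample_rep(np.ones((1, 3)), 5)


# --- model building -------------------------------------------------------


def test_identical_reps_zero_variance_warns():
    reps = [const_rep(1.0) for _ in range(10)]
    with pytest.warns(UserWarning, match="zero-variance"):
        model = build_model(reps, TrainingConfig(n=20, joints=["pelvis"]),
                            rep_duration_s=0.4)
    np.testing.assert_allclose(model.M["pelvis"], 1.0)
    np.testing.assert_allclose(model.S["pelvis"], 0.0)


def test_two_constant_reps_hand_mean_std():
    reps = [const_rep(0.0), const_rep(2.0)]
    model = build_model(
        reps, TrainingConfig(n=20, joints=["pelvis"], min_reps=2),
        rep_duration_s=0.4,
    )
    np.testing.assert_allclose(model.M["pelvis"], 1.0)
    np.testing.assert_allclose(model.S["pelvis"], np.sqrt(2.0))


def test_min_reps_enforced():
    with pytest.raises(ValueError, match="at least 10"):
        build_model([const_rep(0.0)] * 9)


def test_trained_model_shapes_and_variability_bound(squat_model):
    assert squat_model.n == 200
    for j in squat_model.joints:
        assert squat_model.M[j].shape == (3, 200)
        assert squat_model.S[j].shape == (3, 200)
        assert np.all(squat_model.S[j] >= 0)
        # subject variability: +-2 cm offset, +-10% amplitude on <=0.5 m
        # excursions, 5 mm frame noise => S must stay well below 3x that
        assert squat_model.S[j].max() < 3 * (0.02 + 0.05 + 0.005)


# --- index mapping --------------------------------------------------------


def test_map_index_endpoints_and_midpoint(flat_model):
    assert map_index(0, flat_model) == 0
    assert map_index(4000, flat_model) == 199
    assert map_index(2000, flat_model) == 100  # round(99.5) rounds half up
    assert map_index(10_000, flat_model) == 199  # clamped
    with pytest.raises(ValueError):
        map_index(-1, flat_model)


# --- error detection ------------------------------------------------------


def test_detect_error_hand_oracle(flat_model):
    np.testing.assert_allclose(detect_error([0, 0, 0], 5, flat_model, "j"), 0.0)
    np.testing.assert_allclose(
        detect_error([3, 0, 0], 5, flat_model, "j"), [2, 0, 0]
    )
    np.testing.assert_allclose(
        detect_error([2, -2, 1.5], 5, flat_model, "j"), [0, 0, 0]
    )


@given(st.tuples(st.floats(-10, 10), st.floats(-10, 10), st.floats(-10, 10)),
       st.floats(0.5, 4))
def test_detect_error_nonnegative_and_band(p, k):
    n = 200
    model = MovementModel("t", ["j"], n, {"j": np.zeros((3, n))},
                          {"j": np.ones((3, n))})
    e = detect_error(p, 0, model, "j", DetectorConfig(k=k))
    d = np.abs(np.asarray(p))
    assert np.all(e >= 0)
    if k >= 1:  # for k < 1 the else-branch can itself land on zero
        np.testing.assert_array_equal(e == 0, d <= k)


@given(st.floats(0.1, 50))
def test_detect_error_scale_equivariance(c):
    n = 200
    base = MovementModel("t", ["j"], n, {"j": np.full((3, n), 0.3)},
                         {"j": np.full((3, n), 0.8)})
    scaled = MovementModel("t", ["j"], n, {"j": base.M["j"] * c},
                           {"j": base.S["j"] * c})
    p = np.array([3.0, -0.5, 1.7])
    e1 = detect_error(p, 5, base, "j")
    e2 = detect_error(p * c, 5, scaled, "j")
    np.testing.assert_allclose(e2, c * e1, rtol=1e-9)


def test_band_edge_jump(flat_model):
    """e jumps by (k-1)*S at the band edge; continuous for k=1."""
    eps = 1e-9
    inside = detect_error([2 - eps, 0, 0], 0, flat_model, "j")[0]
    outside = detect_error([2 + eps, 0, 0], 0, flat_model, "j")[0]
    assert inside == 0.0
    assert outside == pytest.approx(1.0, abs=1e-6)  # jump of (k-1)*S = 1
    k1 = DetectorConfig(k=1.0)
    lo = detect_error([1 - eps, 0, 0], 0, flat_model, "j", k1)[0]
    hi = detect_error([1 + eps, 0, 0], 0, flat_model, "j", k1)[0]
    assert lo == 0.0 and hi == pytest.approx(0.0, abs=1e-6)


# --- full-repetition assessment ------------------------------------------


def test_training_rep_mostly_inside_band(squat_model):
    rec = generate_recording("squat", n_reps=4, break_s=2,
                             subject_id="EXP01", seed=11)
    events = events_from_boundaries(rec.rep_boundaries)
    assessments = assess_rep(rec, events, squat_model)
    frac_nonzero = np.mean([np.any(a.e > 0) for a in assessments])
    assert frac_nonzero <= 0.10


def test_no_rep_events_vacuous(squat_model, squat_probe):
    assert assess_rep(squat_probe, [], squat_model) == []


def test_missing_modeled_joint_is_error(squat_model):
    rec = const_rep(0.0, length=30, joint="pelvis")
    events = events_from_boundaries([(0, 30)])
    with pytest.raises(SchemaError, match="missing modeled joints"):
        assess_rep(rec, events, squat_model)


def test_assessment_invariants(squat_model, squat_probe):
    from repcoach import ErrorSpec, inject_error

    bad = inject_error(squat_probe, ErrorSpec("III", 4.0), squat_model)
    events = events_from_boundaries(bad.rep_boundaries)
    assessments = assess_rep(bad, events, squat_model)
    assert len(assessments) == 4 * 200 * len(squat_model.joints)
    for a in assessments[::97]:
        a.validate()
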