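import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fast",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")

from repcoach import (
    MovementModel,
    build_model,
    generate_recording,
    split_reps,
)


def make_expert_pool(exercise: str, seed: int = 11, n_subjects: int = 5):
    """Expert demonstrations: n_subjects x 4 repetitions with subject
    variability on (the curated 'high-quality' training pool)."""
    pool = []
    for i in range(1, n_subjects + 1):
        rec = generate_recording(
            exercise, n_reps=4, break_s=2, subject_id=f"EXP{i:02d}", seed=seed
        )
        pool.extend(split_reps(rec))
    return pool


@pytest.fixture(scope="session")
def squat_model() -> MovementModel:
    return build_model(make_expert_pool("squat"), exercise="squat")


@pytest.fixture(scope="session")
def squat_probe():
    """Nominal-subject probe recording used for injection-recovery checks."""
    return generate_recording(
        "squat", n_reps=4, break_s=2, subject_id="PROBE",
        subject_noise=False, seed=99,
    )


@pytest.fixture
def flat_model():
    """One-joint model with zero mean and unit sd everywhere."""
    n = 200
    return MovementModel(
        exercise="test",
        joints=["j"],
        n=n,
        M={"j": np.zeros((3, n))},
        S={"j": np.ones((3, n))},
    )
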