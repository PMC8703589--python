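"""Shared data model for full-body exercise assessment.

The pipeline operates on fixed-rate recordings from a 10-node IMU suit
(per node a 3-axis accelerometer with gravity included, in m/s^2, and a
3-axis gyroscope in deg/s), together with per-frame joint positions of a
uniform avatar (meters, fixed world frame: x = right, y = up, z = front).
The learned reference for one exercise is a :class:`MovementModel` — a
per-joint mean trajectory matrix ``M`` (3 x n) and standard-deviation
matrix ``S`` (3 x n) estimated from expert repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "NODE_NAMES",
    "JOINT_VOCABULARY",
    "SensorNodeSample",
    "Frame",
    "Recording",
    "MovementModel",
    "ErrorAssessment",
    "SchemaError",
    "IntegrityError",
    "RecordingParseError",
    "recordings_equal",
]

#: Canonical sensor-node names, in the fixed order used everywhere
#: (feature vectors, CSV columns).
NODE_NAMES: Tuple[str, ...] = (
    "left_thigh",
    "right_thigh",
    "left_shin",
    "right_shin",
    "left_upper_arm",
    "right_upper_arm",
    "left_forearm",
    "right_forearm",
    "hips",
    "torso",
)

#: Canonical joint vocabulary on the uniform avatar.  Models may use any
#: subset; recordings carry a fixed joint set per file.
JOINT_VOCABULARY: Tuple[str, ...] = (
    "ankle_l",
    "ankle_r",
    "knee_l",
    "knee_r",
    "hip_l",
    "hip_r",
    "pelvis",
    "lower_spine",
    "upper_spine",
    "clavicle_l",
    "clavicle_r",
    "shoulder_l",
    "shoulder_r",
    "elbow_l",
    "elbow_r",
    "wrist_l",
    "wrist_r",
)

BREAK_CONDITIONS = ("long", "short", "none", "n/a")

NEGATIVE_LABEL = "NEGATIVE_NONE"


class SchemaError(ValueError):
    """A file or object does not conform to the documented schema."""


class IntegrityError(ValueError):
    """Internally inconsistent derived results (e.g. metrics vs counts)."""


class RecordingParseError(ValueError):
    """A row/line of an on-disk recording could not be parsed."""


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise SchemaError(f"{name} must be a 3-vector, got shape {v.shape}")
    return v


@dataclass
class SensorNodeSample:
    """One IMU node reading: accelerometer (m/s^2, gravity included) and
    gyroscope (deg/s); magnetometer and orientation quaternion are carried
    for completeness but never used in any computation."""

    accel: np.ndarray
    gyro: np.ndarray
    mag: Optional[np.ndarray] = None
    quat: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.accel = _as_vec3(self.accel, "accel")
        self.gyro = _as_vec3(self.gyro, "gyro")
        if self.mag is not None:
            self.mag = _as_vec3(self.mag, "mag")
        if self.quat is not None:
            self.quat = np.asarray(self.quat, dtype=float)

    def validate(self) -> None:
        if not (np.isfinite(self.accel).all() and np.isfinite(self.gyro).all()):
            raise SchemaError("accel and gyro must be finite")
        if self.quat is not None:
            if self.quat.shape != (4,):
                raise SchemaError("orientation quaternion must have 4 components")
            n = float(np.linalg.norm(self.quat))
            if abs(n - 1.0) > 1e-6:
                raise SchemaError(f"orientation quaternion norm {n} != 1")


@dataclass
class Frame:
    """One time step: timestamp (ms since recording start), the 10 node
    samples, and joint positions (meters) on the uniform avatar."""

    t_ms: int
    nodes: Dict[str, SensorNodeSample]
    joints: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_ms = int(self.t_ms)
        self.joints = {k: _as_vec3(v, f"joint {k}") for k, v in self.joints.items()}

    def validate(self) -> None:
        if self.t_ms < 0:
            raise SchemaError("frame timestamp must be non-negative")
        if set(self.nodes) != set(NODE_NAMES):
            missing = set(NODE_NAMES) - set(self.nodes)
            extra = set(self.nodes) - set(NODE_NAMES)
            raise SchemaError(
                f"frame node set must be the 10 canonical nodes "
                f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
            )
        for s in self.nodes.values():
            s.validate()


@dataclass
class Recording:
    """A fixed-rate multi-node sensor stream with joint positions and
    optional per-sample labels / ground-truth repetition boundaries.

    ``rep_boundaries`` are half-open frame-index ranges ``[start, end)``,
    non-overlapping and ordered.  Labels, when present, are one of
    ``<exercise>_POSE``, ``<exercise>_REP`` or ``NEGATIVE_NONE`` per frame.
    """

    frames: List[Frame]
    rate_hz: float = 50.0
    subject_id: str = ""
    exercise: Optional[str] = None
    break_condition: str = "n/a"
    labels: Optional[List[str]] = None
    rep_boundaries: Optional[List[Tuple[int, int]]] = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def times_ms(self) -> np.ndarray:
        return np.array([f.t_ms for f in self.frames], dtype=np.int64)

    def gyro(self, node: str) -> np.ndarray:
        """(n_frames, 3) gyroscope stream of one node, deg/s."""
        try:
            return np.stack([f.nodes[node].gyro for f in self.frames])
        except KeyError:
            raise SchemaError(f"node {node!r} missing from recording") from None

    def accel(self, node: str) -> np.ndarray:
        """(n_frames, 3) accelerometer stream of one node, m/s^2."""
        try:
            return np.stack([f.nodes[node].accel for f in self.frames])
        except KeyError:
            raise SchemaError(f"node {node!r} missing from recording") from None

    def joint(self, name: str) -> np.ndarray:
        """(n_frames, 3) position trajectory of one joint, meters."""
        try:
            return np.stack([f.joints[name] for f in self.frames])
        except KeyError:
            raise SchemaError(f"joint {name!r} missing from recording") from None

    def joint_names(self) -> List[str]:
        return list(self.frames[0].joints) if self.frames else []

    def validate(self) -> None:
        if not self.frames:
            raise SchemaError("recording has no frames")
        if self.break_condition not in BREAK_CONDITIONS:
            raise SchemaError(f"unknown break condition {self.break_condition!r}")
        joint_set = set(self.frames[0].joints)
        for f in self.frames:
            f.validate()
            if set(f.joints) != joint_set:
                raise SchemaError("joint set must be fixed across frames")
        t = self.times_ms()
        if np.any(np.diff(t) <= 0):
            raise SchemaError("timestamps must be strictly increasing")
        nominal = round(1000.0 / self.rate_hz)
        if np.any(np.abs(np.diff(t) - nominal) > 1):
            bad = int(np.argmax(np.abs(np.diff(t) - nominal) > 1))
            raise SchemaError(
                f"inter-frame delta at frame {bad + 1} deviates more than "
                f"1 ms from nominal {nominal} ms"
            )
        if self.labels is not None and len(self.labels) != len(self.frames):
            raise SchemaError("labels length must equal number of frames")
        if self.rep_boundaries is not None:
            prev_end = 0
            for a, b in self.rep_boundaries:
                if not (0 <= a < b <= len(self.frames)):
                    raise SchemaError(f"rep boundary ({a}, {b}) out of range")
                if a < prev_end:
                    raise SchemaError("rep boundaries must be ordered, non-overlapping")
                prev_end = b


@dataclass
class MovementModel:
    """Per-joint probabilistic movement model learned from expert reps.

    ``M[joint]`` and ``S[joint]`` are 3 x n matrices (rows = x, y, z) of
    per-time-sample mean position and standard deviation; ``n`` samples
    span one repetition of ``rep_duration_s`` seconds.
    """

    exercise: str
    joints: List[str]
    n: int
    M: Dict[str, np.ndarray]
    S: Dict[str, np.ndarray]
    rep_duration_s: float = 4.0
    rate_hz: float = 50.0

    @property
    def rep_duration_ms(self) -> float:
        return self.rep_duration_s * 1000.0

    def validate(self) -> None:
        if self.n != round(self.rep_duration_s * self.rate_hz):
            raise SchemaError(
                f"n={self.n} inconsistent with rep_duration_s*rate_hz="
                f"{self.rep_duration_s * self.rate_hz}"
            )
        for j in self.joints:
            if j not in self.M or j not in self.S:
                raise SchemaError(f"joint {j!r} missing M or S matrix")
            if self.M[j].shape != (3, self.n) or self.S[j].shape != (3, self.n):
                raise SchemaError(
                    f"joint {j!r}: M/S must have shape (3, {self.n})"
                )
            if np.any(self.S[j] < 0):
                raise SchemaError(f"joint {j!r}: S entries must be >= 0")


@dataclass
class ErrorAssessment:
    """Per-joint, per-frame execution-error record.

    ``e`` is the non-negative error magnitude per axis (meters),
    ``e_direction`` the signed version, ``e_intensity`` the signed error in
    sigma units, ``h_power`` the haptic power per axis in [0, 1], and
    ``direction_bin`` the binned direction label (haptics vocabulary).
    """

    joint: str
    frame_index: int
    e: np.ndarray
    e_direction: np.ndarray
    e_intensity: np.ndarray
    h_power: np.ndarray
    direction_bin: str

    def validate(self) -> None:
        if np.any(self.e < 0):
            raise IntegrityError("e must be elementwise non-negative")
        if not np.allclose(np.abs(self.e_direction), self.e):
            raise IntegrityError("|e_direction| must equal e elementwise")
        if np.any(self.h_power < 0) or np.any(self.h_power > 1):
            raise IntegrityError("h_power must lie in [0, 1] per axis")


def _samples_equal(a: SensorNodeSample, b: SensorNodeSample, rtol: float) -> bool:
    def close(x, y):
        if x is None or y is None:
            return x is None and y is None
        return np.allclose(x, y, rtol=rtol, atol=rtol)

    return (
        close(a.accel, b.accel)
        and close(a.gyro, b.gyro)
        and close(a.mag, b.mag)
        and close(a.quat, b.quat)
    )


def recordings_equal(a: Recording, b: Recording, rtol: float = 1e-9) -> bool:
    """Structural equality of two recordings up to float round-trip noise."""
    if (
        a.n_frames != b.n_frames
        or round(a.rate_hz, 6) != round(b.rate_hz, 6)
        or a.subject_id != b.subject_id
        or a.exercise != b.exercise
        or a.break_condition != b.break_condition
        or (a.labels or None) != (b.labels or None)
        or (list(map(tuple, a.rep_boundaries)) if a.rep_boundaries else None)
        != (list(map(tuple, b.rep_boundaries)) if b.rep_boundaries else None)
    ):
        return False
    for fa, fb in zip(a.frames, b.frames):
        if fa.t_ms != fb.t_ms or set(fa.nodes) != set(fb.nodes):
            return False
        if set(fa.joints) != set(fb.joints):
            return False
        if not all(_samples_equal(fa.nodes[n], fb.nodes[n], rtol) for n in fa.nodes):
            return False
        if not all(
            np.allclose(fa.joints[j], fb.joints[j], rtol=rtol, atol=rtol)
            for j in fa.joints
        ):
            return False
    return True
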