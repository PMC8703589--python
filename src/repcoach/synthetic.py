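"""Labeled, ground-truthed synthetic recordings of the study protocol.

The generator emulates the data-collection protocol: 50 Hz streams from
the 10-node suit, repetitions of fixed 4 s duration (2 s concentric +
2 s eccentric), break conditions of 2 / 1 / 0 s between repetitions,
per-sample labels (``<exercise>_POSE`` during holds, ``<exercise>_REP``
during repetitions, ``NEGATIVE_NONE`` before/after the set) and exact
repetition boundaries as ground truth.

Joint trajectories follow a half-cosine between the starting pose and the
bottom position (zero velocity at the endpoints, matching the stationarity
assumption at repetition boundaries).  Gyroscope signals are parametric —
per 2 s phase a sharp-onset burst ``A * sin(pi*v)**0.25`` whose magnitude
structure (near-zero during holds, well above the moving threshold during
repetitions, fast onset/offset) is what the segmenter consumes; they are
not the output of a physics model.  Accelerometers hold a posture-specific
gravity vector that interpolates between pose and bottom orientation.

Subject variability is a per-subject random amplitude scale (±10%), a
whole-body positional offset (±2 cm), a per-node accelerometer bias, a
small per-repetition amplitude jitter, and slow postural sway while the
subject holds still (so pose frames are never a degenerate repeated
point), all seeded from (seed, subject_id).
``frame_noise_sd`` (meters) sets white positional noise on joints and
proportional sensor noise (accel 25x in m/s^2, gyro 200x in deg/s).

Error injection displaces chosen joints along each error type's canonical
direction by ``severity`` local standard deviations of an expert model,
shaped by a plateaued window over the repetition (zero at the endpoints):

* type I  — torso lean: spine/clavicle/shoulder joints toward +z (front)
  for squat and lunge; the arched-back pattern for push-ups (pelvis,
  lower spine and hips toward -y, upper spine/clavicle/shoulders -z).
* type II — knees toward the midline (squat, lunge); elbows outward
  (push-up).
* type III — partial repetition: every joint whose modeled vertical
  excursion exceeds 5 cm is raised toward +y, so the movement trough is
  too shallow; knee and ankle height does not change in a squat or lunge,
  so those joints stay error-free by construction.
"""

from __future__ import annotations

import copy
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import (
    NEGATIVE_LABEL,
    NODE_NAMES,
    Frame,
    MovementModel,
    Recording,
    SensorNodeSample,
)

__all__ = [
    "ExerciseTemplate",
    "ErrorSpec",
    "get_template",
    "generate_recording",
    "generate_dataset",
    "inject_error",
    "canonical_error_pattern",
    "BREAK_NAME",
]

GRAVITY = 9.81
#: sensor-noise scale factors relative to frame_noise_sd (meters)
ACCEL_NOISE_PER_M = 25.0  # m/s^2 per meter of positional noise
GYRO_NOISE_PER_M = 200.0  # deg/s per meter of positional noise
#: postural-sway amplitudes during holds (part of subject variability)
SWAY_ACCEL = 0.25  # m/s^2
SWAY_GYRO = 0.8  # deg/s

BREAK_NAME = {2: "long", 1: "short", 0: "none"}


@dataclass
class ExerciseTemplate:
    """Parametric description of one exercise's clean execution."""

    name: str
    pose_joints: Dict[str, np.ndarray]
    bottom_joints: Dict[str, np.ndarray]
    accel_pose: Dict[str, np.ndarray]
    accel_bottom: Dict[str, np.ndarray]
    accel_negative: Dict[str, np.ndarray]
    gyro_amp: Dict[str, np.ndarray]
    source_node: str
    rep_duration_s: float = 4.0

    def __post_init__(self) -> None:
        conv = lambda d: {k: np.asarray(v, dtype=float) for k, v in d.items()}
        self.pose_joints = conv(self.pose_joints)
        self.bottom_joints = conv(self.bottom_joints)
        self.accel_pose = conv(self.accel_pose)
        self.accel_bottom = conv(self.accel_bottom)
        self.accel_negative = conv(self.accel_negative)
        self.gyro_amp = conv(self.gyro_amp)


@dataclass
class ErrorSpec:
    """error_type in {"I", "II", "III"}; severity in local sigma units of
    the expert model (0 reproduces the clean recording)."""

    error_type: str
    severity: float = 4.0
    affected_joints: Optional[List[str]] = None

    def __post_init__(self) -> None:
        if self.error_type not in ("I", "II", "III"):
            raise ValueError(f"unknown error type {self.error_type!r}")
        if self.severity < 0:
            raise ValueError("severity must be >= 0")


def _squat_template() -> ExerciseTemplate:
    drop = 0.45  # hip descent depth, meters
    pose = {
        "pelvis": (0.00, 1.00, 0.00),
        "lower_spine": (0.00, 1.15, 0.00),
        "upper_spine": (0.00, 1.35, 0.00),
        "clavicle_l": (-0.08, 1.45, 0.00),
        "clavicle_r": (0.08, 1.45, 0.00),
        "shoulder_l": (-0.20, 1.45, 0.00),
        "shoulder_r": (0.20, 1.45, 0.00),
        "elbow_l": (-0.45, 1.45, 0.10),
        "elbow_r": (0.45, 1.45, 0.10),
        "wrist_l": (-0.70, 1.45, 0.15),
        "wrist_r": (0.70, 1.45, 0.15),
        "hip_l": (-0.12, 0.95, 0.00),
        "hip_r": (0.12, 0.95, 0.00),
        "knee_l": (-0.13, 0.50, 0.02),
        "knee_r": (0.13, 0.50, 0.02),
        "ankle_l": (-0.14, 0.08, 0.00),
        "ankle_r": (0.14, 0.08, 0.00),
    }
    bottom = {j: np.array(p, dtype=float) for j, p in pose.items()}
    for j in ("pelvis", "hip_l", "hip_r"):
        bottom[j] = bottom[j] + [0, -drop, -0.05]
    for j in ("lower_spine", "upper_spine"):
        bottom[j] = bottom[j] + [0, -drop, 0.03]
    for j in ("clavicle_l", "clavicle_r", "shoulder_l", "shoulder_r",
              "elbow_l", "elbow_r", "wrist_l", "wrist_r"):
        bottom[j] = bottom[j] + [0, -drop, 0.06]
    for j in ("knee_l", "knee_r"):
        bottom[j] = bottom[j] + [0, 0.0, 0.12]  # knees travel forward, not down
    accel_pose = {
        "left_thigh": (0, GRAVITY, 0),
        "right_thigh": (0, GRAVITY, 0),
        "left_shin": (0, GRAVITY, 0),
        "right_shin": (0, GRAVITY, 0),
        "left_upper_arm": (GRAVITY * 0.9, GRAVITY * 0.44, 0),  # arms out
        "right_upper_arm": (-GRAVITY * 0.9, GRAVITY * 0.44, 0),
        "left_forearm": (GRAVITY, 0, 0),
        "right_forearm": (-GRAVITY, 0, 0),
        "hips": (0, GRAVITY, 0),
        "torso": (0, GRAVITY, 0),
    }
    accel_bottom = {
        "left_thigh": (0, 1.5, GRAVITY * 0.98),  # thigh near horizontal
        "right_thigh": (0, 1.5, GRAVITY * 0.98),
        "left_shin": (0, GRAVITY * 0.9, -GRAVITY * 0.42),
        "right_shin": (0, GRAVITY * 0.9, -GRAVITY * 0.42),
        "left_upper_arm": (GRAVITY * 0.85, GRAVITY * 0.35, 3.0),
        "right_upper_arm": (-GRAVITY * 0.85, GRAVITY * 0.35, 3.0),
        "left_forearm": (GRAVITY * 0.95, 0, 3.0),
        "right_forearm": (-GRAVITY * 0.95, 0, 3.0),
        "hips": (0, GRAVITY * 0.9, GRAVITY * 0.42),
        "torso": (0, GRAVITY * 0.95, GRAVITY * 0.3),
    }
    accel_negative = {  # relaxed standing, arms hanging down
        n: (0, GRAVITY, 0) for n in NODE_NAMES
    }
    accel_negative["left_upper_arm"] = (0.8, GRAVITY * 0.98, 0)
    accel_negative["right_upper_arm"] = (-0.8, GRAVITY * 0.98, 0)
    accel_negative["left_forearm"] = (0.5, GRAVITY * 0.99, 0)
    accel_negative["right_forearm"] = (-0.5, GRAVITY * 0.99, 0)
    gyro_amp = {
        "left_thigh": (75, 8, 5),
        "right_thigh": (80, 8, 5),
        "left_shin": (55, 6, 4),
        "right_shin": (55, 6, 4),
        "left_upper_arm": (40, 10, 6),
        "right_upper_arm": (40, 10, 6),
        "left_forearm": (38, 8, 5),
        "right_forearm": (38, 8, 5),
        "hips": (45, 5, 4),
        "torso": (40, 5, 4),
    }
    return ExerciseTemplate(
        name="squat",
        pose_joints=pose,
        bottom_joints=bottom,
        accel_pose=accel_pose,
        accel_bottom=accel_bottom,
        accel_negative=accel_negative,
        gyro_amp=gyro_amp,
        source_node="right_thigh",
    )


def _lunge_template() -> ExerciseTemplate:
    t = _squat_template()
    drop = 0.35
    pose = {j: np.array(p) for j, p in t.pose_joints.items()}
    # staggered stance: right leg forward
    for j, dz in (("hip_r", 0.10), ("knee_r", 0.30), ("ankle_r", 0.38)):
        pose[j] = pose[j] + [0, 0, dz]
    for j, dz in (("knee_l", -0.18), ("ankle_l", -0.35)):
        pose[j] = pose[j] + [0, 0, dz]
    pose["knee_l"][1] = 0.45
    # arms on hips rather than outstretched
    for j, p in (("elbow_l", (-0.25, 1.10, 0.05)), ("elbow_r", (0.25, 1.10, 0.05)),
                 ("wrist_l", (-0.14, 1.00, 0.05)), ("wrist_r", (0.14, 1.00, 0.05))):
        pose[j] = np.array(p, dtype=float)
    bottom = {j: np.array(p) for j, p in pose.items()}
    for j in ("pelvis", "hip_l", "hip_r", "lower_spine", "upper_spine",
              "clavicle_l", "clavicle_r", "shoulder_l", "shoulder_r",
              "elbow_l", "elbow_r", "wrist_l", "wrist_r"):
        bottom[j] = bottom[j] + [0, -drop, 0]
    bottom["knee_l"] = bottom["knee_l"] + [0, -0.32, 0]  # rear knee to floor
    accel_pose = dict(t.accel_negative)  # arms down, upright trunk
    accel_pose["left_thigh"] = (0, GRAVITY * 0.97, -2.0)
    accel_pose["right_thigh"] = (0, GRAVITY * 0.97, 2.0)
    accel_pose["left_shin"] = (0, GRAVITY * 0.95, -2.5)
    accel_pose["right_shin"] = (0, GRAVITY * 0.95, 2.5)
    accel_bottom = {
        "left_thigh": (0, 2.0, -GRAVITY * 0.97),  # rear thigh near vertical drop
        "right_thigh": (0, 1.8, GRAVITY * 0.97),
        "left_shin": (0, GRAVITY * 0.4, -GRAVITY * 0.9),
        "right_shin": (0, GRAVITY * 0.98, 0.5),
        "left_upper_arm": (0.8, GRAVITY * 0.95, 1.5),
        "right_upper_arm": (-0.8, GRAVITY * 0.95, 1.5),
        "left_forearm": (0.5, GRAVITY * 0.96, 1.5),
        "right_forearm": (-0.5, GRAVITY * 0.96, 1.5),
        "hips": (0, GRAVITY * 0.97, 1.5),
        "torso": (0, GRAVITY * 0.98, 1.0),
    }
    gyro_amp = {
        "left_thigh": (70, 7, 5),
        "right_thigh": (78, 7, 5),
        "left_shin": (60, 6, 4),
        "right_shin": (45, 6, 4),
        "left_upper_arm": (36, 8, 5),
        "right_upper_arm": (36, 8, 5),
        "left_forearm": (35, 7, 4),
        "right_forearm": (35, 7, 4),
        "hips": (42, 5, 4),
        "torso": (38, 5, 4),
    }
    return ExerciseTemplate(
        name="lunge",
        pose_joints=pose,
        bottom_joints=bottom,
        accel_pose=accel_pose,
        accel_bottom=accel_bottom,
        accel_negative=t.accel_negative,
        gyro_amp=gyro_amp,
        source_node="right_thigh",
    )


def _pushup_template() -> ExerciseTemplate:
    pose = {  # top of the plank, facing the floor, head toward +z
        "pelvis": (0.00, 0.32, 0.00),
        "lower_spine": (0.00, 0.35, 0.15),
        "upper_spine": (0.00, 0.38, 0.40),
        "clavicle_l": (-0.08, 0.40, 0.50),
        "clavicle_r": (0.08, 0.40, 0.50),
        "shoulder_l": (-0.20, 0.40, 0.50),
        "shoulder_r": (0.20, 0.40, 0.50),
        "elbow_l": (-0.24, 0.22, 0.50),
        "elbow_r": (0.24, 0.22, 0.50),
        "wrist_l": (-0.26, 0.04, 0.50),
        "wrist_r": (0.26, 0.04, 0.50),
        "hip_l": (-0.12, 0.31, -0.02),
        "hip_r": (0.12, 0.31, -0.02),
        "knee_l": (-0.12, 0.18, -0.45),
        "knee_r": (0.12, 0.18, -0.45),
        "ankle_l": (-0.13, 0.10, -0.85),
        "ankle_r": (0.13, 0.10, -0.85),
    }
    dip = 0.22
    bottom = {j: np.array(p, dtype=float) for j, p in pose.items()}
    for j in ("pelvis", "lower_spine", "upper_spine", "clavicle_l", "clavicle_r",
              "shoulder_l", "shoulder_r", "hip_l", "hip_r"):
        bottom[j] = bottom[j] + [0, -dip, 0]
    for j in ("elbow_l", "elbow_r"):
        bottom[j] = bottom[j] + [0, -0.08, 0]
    for j in ("knee_l", "knee_r"):
        bottom[j] = bottom[j] + [0, -0.06, 0]
    accel_pose = {  # trunk horizontal: gravity mostly along node z/x axes
        "left_thigh": (0, 2.0, GRAVITY * 0.96),
        "right_thigh": (0, 2.0, GRAVITY * 0.96),
        "left_shin": (0, 1.5, GRAVITY * 0.97),
        "right_shin": (0, 1.5, GRAVITY * 0.97),
        "left_upper_arm": (0, GRAVITY * 0.98, 1.0),  # upper arm vertical
        "right_upper_arm": (0, GRAVITY * 0.98, 1.0),
        "left_forearm": (0, GRAVITY * 0.97, 1.5),
        "right_forearm": (0, GRAVITY * 0.97, 1.5),
        "hips": (0, 1.0, GRAVITY * 0.98),
        "torso": (0, 1.5, GRAVITY * 0.97),
    }
    accel_bottom = {
        "left_thigh": (0, 2.2, GRAVITY * 0.95),
        "right_thigh": (0, 2.2, GRAVITY * 0.95),
        "left_shin": (0, 1.6, GRAVITY * 0.96),
        "right_shin": (0, 1.6, GRAVITY * 0.96),
        "left_upper_arm": (GRAVITY * 0.7, GRAVITY * 0.65, 1.5),  # elbows bent
        "right_upper_arm": (-GRAVITY * 0.7, GRAVITY * 0.65, 1.5),
        "left_forearm": (1.0, GRAVITY * 0.93, 2.5),
        "right_forearm": (-1.0, GRAVITY * 0.93, 2.5),
        "hips": (0, 1.2, GRAVITY * 0.97),
        "torso": (0, 1.8, GRAVITY * 0.95),
    }
    accel_negative = {n: (0, GRAVITY, 0) for n in NODE_NAMES}
    accel_negative["left_upper_arm"] = (0.8, GRAVITY * 0.98, 0)
    accel_negative["right_upper_arm"] = (-0.8, GRAVITY * 0.98, 0)
    accel_negative["left_forearm"] = (0.5, GRAVITY * 0.99, 0)
    accel_negative["right_forearm"] = (-0.5, GRAVITY * 0.99, 0)
    gyro_amp = {
        "left_thigh": (36, 5, 4),
        "right_thigh": (36, 5, 4),
        "left_shin": (35, 5, 3),
        "right_shin": (35, 5, 3),
        "left_upper_arm": (58, 8, 5),
        "right_upper_arm": (60, 8, 5),
        "left_forearm": (50, 7, 5),
        "right_forearm": (50, 7, 5),
        "hips": (36, 4, 3),
        "torso": (38, 4, 3),
    }
    return ExerciseTemplate(
        name="pushup",
        pose_joints=pose,
        bottom_joints=bottom,
        accel_pose=accel_pose,
        accel_bottom=accel_bottom,
        accel_negative=accel_negative,
        gyro_amp=gyro_amp,
        source_node="right_upper_arm",
    )


_TEMPLATES = {
    "squat": _squat_template,
    "lunge": _lunge_template,
    "pushup": _pushup_template,
}


def get_template(name: str) -> ExerciseTemplate:
    try:
        return _TEMPLATES[name]()
    except KeyError:
        raise ValueError(
            f"unknown exercise template {name!r}; choose from {sorted(_TEMPLATES)}"
        ) from None


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(subject_id.encode())])


def _burst(u: np.ndarray) -> np.ndarray:
    """Signed sin^(1/4) gyro burst over one repetition (u in [0, 1]):
    fast onset/offset per 2 s phase, zero exactly at the endpoints and the
    turnaround."""
    v = np.where(u < 0.5, u * 2.0, (u - 0.5) * 2.0)
    mag = np.clip(np.sin(np.pi * v), 0.0, None) ** 0.25
    return np.where(u < 0.5, mag, -mag)


def generate_recording(
    template,
    n_reps: int = 4,
    break_s: int = 2,
    subject_id: str = "S01",
    subject_noise: bool = True,
    frame_noise_sd: float = 0.005,
    seed: int = 0,
    rate_hz: float = 50.0,
    lead_in_s: float = 2.0,
    lead_out_s: float = 2.0,
) -> Recording:
    """Generate one labeled set of repetitions with exact ground truth.

    The lead-in is half NEGATIVE (idle stance) and half POSE (starting
    pose taken); breaks between repetitions are POSE; the lead-out is
    NEGATIVE.  Identical arguments always produce an identical recording.
    """
    if isinstance(template, str):
        template = get_template(template)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if frame_noise_sd < 0:
        raise ValueError("frame_noise_sd must be >= 0")
    if break_s not in (0, 1, 2):
        raise ValueError("break_s must be one of {0, 1, 2}")

    dt_ms = round(1000.0 / rate_hz)
    rep_frames = round(template.rep_duration_s * rate_hz)
    neg_in = round(lead_in_s / 2 * rate_hz)
    pose_in = round(lead_in_s * rate_hz) - neg_in
    brk = round(break_s * rate_hz)
    neg_out = round(lead_out_s * rate_hz)

    # frame-wise schedule: label, rep index (-1 outside), phase u in [0,1]
    labels: List[str] = []
    rep_idx: List[int] = []
    segments: List[Tuple[str, int]] = [("NEG", neg_in), ("POSE", pose_in)]
    for k in range(n_reps):
        segments.append(("REP", rep_frames))
        if k < n_reps - 1 and brk > 0:
            segments.append(("POSE", brk))
    segments.append(("NEG", neg_out))

    ex = template.name
    boundaries: List[Tuple[int, int]] = []
    phase = []
    rep_counter = 0
    for kind, length in segments:
        start = len(labels)
        for i in range(length):
            if kind == "REP":
                labels.append(f"{ex}_REP")
                rep_idx.append(rep_counter)
                phase.append(i / rep_frames)
            else:
                labels.append(f"{ex}_POSE" if kind == "POSE" else NEGATIVE_LABEL)
                rep_idx.append(-1)
                phase.append(0.0)
        if kind == "REP":
            boundaries.append((start, start + length))
            rep_counter += 1
    n_frames = len(labels)
    u = np.asarray(phase)
    rep_idx_arr = np.asarray(rep_idx)
    in_rep = rep_idx_arr >= 0
    is_neg = np.asarray([l == NEGATIVE_LABEL for l in labels])

    # subject variability, incl. slow postural sway while holding still
    t_s = np.arange(n_frames) / rate_hz
    hold = ~in_rep
    if subject_noise:
        srng = _subject_rng(seed, subject_id)
        amp_scale = float(srng.uniform(0.9, 1.1))
        offset = srng.uniform(-0.02, 0.02, size=3)
        accel_bias = {n: srng.normal(0.0, 0.15, size=3) for n in NODE_NAMES}
        rep_jitter = srng.uniform(-0.02, 0.02, size=n_reps)
        sway_f = float(srng.uniform(0.3, 0.5))
        sway_phase = {n: srng.uniform(0, 2 * np.pi, size=3) for n in NODE_NAMES}

        def sway(n, amplitude):
            w = amplitude * np.sin(
                2 * np.pi * sway_f * t_s[:, None] + sway_phase[n][None, :]
            )
            return np.where(hold[:, None], w, 0.0)

    else:
        amp_scale = 1.0
        offset = np.zeros(3)
        accel_bias = {n: np.zeros(3) for n in NODE_NAMES}
        rep_jitter = np.zeros(n_reps)
        sway = lambda n, amplitude: 0.0

    nrng = np.random.default_rng(
        [seed & 0x7FFFFFFF, 0x5EED, zlib.crc32(subject_id.encode()), n_reps, brk]
    )

    # movement depth profile: half-cosine down (2 s) and up (2 s)
    s = np.where(in_rep, 0.5 * (1.0 - np.cos(2.0 * np.pi * u)), 0.0)
    scale = np.where(
        in_rep, amp_scale * (1.0 + rep_jitter[np.clip(rep_idx_arr, 0, None)]), 1.0
    )
    s = s * scale

    burst = np.where(in_rep, _burst(u), 0.0)

    # precompute per-node streams
    accel = {}
    gyro = {}
    for n in NODE_NAMES:
        a_pose = template.accel_pose[n]
        a_bot = template.accel_bottom[n]
        a_neg = template.accel_negative[n]
        base = a_pose[None, :] + s[:, None] * (a_bot - a_pose)[None, :]
        base[is_neg] = a_neg
        base = base + accel_bias[n] + sway(n, SWAY_ACCEL)
        if frame_noise_sd > 0:
            base = base + nrng.normal(
                0.0, ACCEL_NOISE_PER_M * frame_noise_sd, size=base.shape
            )
        accel[n] = base
        amp = template.gyro_amp[n][None, :] * scale[:, None]
        g = burst[:, None] * amp + sway(n, SWAY_GYRO)
        if frame_noise_sd > 0:
            g = g + nrng.normal(0.0, GYRO_NOISE_PER_M * frame_noise_sd, size=g.shape)
        gyro[n] = g

    joints = {}
    for j, p0 in template.pose_joints.items():
        disp = template.bottom_joints[j] - p0
        traj = p0[None, :] + s[:, None] * disp[None, :] + offset
        if frame_noise_sd > 0:
            traj = traj + nrng.normal(0.0, frame_noise_sd, size=traj.shape)
        joints[j] = traj

    joint_names = list(template.pose_joints)
    frames = [
        Frame(
            t_ms=f * dt_ms,
            nodes={
                n: SensorNodeSample(accel=accel[n][f], gyro=gyro[n][f])
                for n in NODE_NAMES
            },
            joints={j: joints[j][f] for j in joint_names},
        )
        for f in range(n_frames)
    ]
    return Recording(
        frames=frames,
        rate_hz=rate_hz,
        subject_id=subject_id,
        exercise=ex,
        break_condition=BREAK_NAME.get(break_s, "n/a"),
        labels=labels,
        rep_boundaries=boundaries,
    )


def generate_dataset(
    exercises: Sequence[str] = ("squat", "lunge", "pushup"),
    subjects: Sequence[str] = tuple(f"S{i:02d}" for i in range(1, 16)),
    n_reps: int = 4,
    break_s: int = 2,
    frame_noise_sd: float = 0.005,
    seed: int = 0,
    subject_noise: bool = True,
) -> List[Recording]:
    """One recording per (subject, exercise) under a common seed."""
    return [
        generate_recording(
            ex,
            n_reps=n_reps,
            break_s=break_s,
            subject_id=s,
            subject_noise=subject_noise,
            frame_noise_sd=frame_noise_sd,
            seed=seed,
        )
        for s in subjects
        for ex in exercises
    ]


_TORSO_JOINTS = ("lower_spine", "upper_spine", "clavicle_l", "clavicle_r",
                 "shoulder_l", "shoulder_r")
_PUSHUP_LOW = ("pelvis", "lower_spine", "hip_l", "hip_r")
_PUSHUP_HIGH = ("upper_spine", "clavicle_l", "clavicle_r", "shoulder_l", "shoulder_r")
MOVING_JOINT_MIN_RANGE = 0.05  # m of vertical excursion to count as "moving"


def canonical_error_pattern(
    error_type: str,
    exercise: str,
    model: MovementModel,
    affected_joints: Optional[Sequence[str]] = None,
) -> Dict[str, Tuple[int, float]]:
    """Map joint -> (axis index, sign) for an error type on an exercise."""
    avail = set(model.joints)
    pattern: Dict[str, Tuple[int, float]] = {}
    if error_type == "I":
        if exercise == "pushup":
            for j in _PUSHUP_LOW:
                pattern[j] = (1, -1.0)
            for j in _PUSHUP_HIGH:
                pattern[j] = (2, -1.0)
        else:
            for j in _TORSO_JOINTS:
                pattern[j] = (2, +1.0)
    elif error_type == "II":
        if exercise == "pushup":
            pattern["elbow_l"] = (0, -1.0)  # outward = away from midline
            pattern["elbow_r"] = (0, +1.0)
        else:
            pattern["knee_l"] = (0, +1.0)  # toward the midline
            pattern["knee_r"] = (0, -1.0)
    else:  # type III: raise the trough of every joint that actually descends
        for j in model.joints:
            if np.ptp(model.M[j][1]) > MOVING_JOINT_MIN_RANGE:
                pattern[j] = (1, +1.0)
    if affected_joints is not None:
        pattern = {j: pattern[j] for j in affected_joints if j in pattern}
    return {j: v for j, v in pattern.items() if j in avail}


def _plateau(u: np.ndarray, ramp: float = 0.15) -> np.ndarray:
    """Smoothstep up over the first ``ramp`` of the rep, plateau at 1,
    smoothstep down over the last ``ramp`` (zero at both endpoints)."""
    x = np.clip(np.minimum(u, 1.0 - u) / ramp, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def inject_error(rec: Recording, spec: ErrorSpec, model: MovementModel) -> Recording:
    """Displace affected joints by ``severity`` local standard deviations
    along the error type's canonical direction inside every repetition.

    Labels and boundaries are unchanged; severity 0 returns an identical
    copy.
    """
    if not rec.rep_boundaries:
        raise ValueError("recording has no rep boundaries; segment it first")
    out = copy.deepcopy(rec)
    pattern = canonical_error_pattern(
        spec.error_type, rec.exercise or model.exercise, model, spec.affected_joints
    )
    for a, b in out.rep_boundaries:
        L = b - a
        u = np.arange(L) / L
        shape = _plateau(u)
        cols = np.minimum(
            np.floor(u * model.n + 0.5).astype(int), model.n - 1
        )
        for j, (axis, sign) in pattern.items():
            sd = model.S[j][axis, cols]
            for i in range(L):
                out.frames[a + i].joints[j][axis] += (
                    sign * spec.severity * sd[i] * shape[i]
                )
    return out
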