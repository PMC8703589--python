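"""Probabilistic movement models: learning and per-frame error detection.

A model for one exercise holds, per joint, a mean trajectory ``M`` (3 x n)
and a standard-deviation trajectory ``S`` (3 x n) estimated from expert
repetitions resampled onto a common n-point grid.  At assessment time the
elapsed time since the repetition start maps a frame to a column ``i``
(repetition duration is fixed, so no time warping is needed), and the
per-axis deviation ``d = |M_i - p|`` is converted to an error magnitude

    e = 0        if d <= k * S_i
    e = d - S_i  otherwise

with ``k`` a confidence multiplier (k = 2 covers ~95% of expert
variation per axis).  Note the else-branch subtracts one S_i, not k*S_i:
the error magnitude jumps by (k-1)*S_i at the band edge.  That
discontinuity is intentional and kept as designed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import haptics
from .segment import SegmentationEvent, pairs_from_events
from .types import ErrorAssessment, MovementModel, Recording, SchemaError

__all__ = [
    "TrainingConfig",
    "DetectorConfig",
    "resample_rep",
    "split_reps",
    "build_model",
    "map_index",
    "detect_error",
    "assess_rep",
]


@dataclass
class TrainingConfig:
    """``n`` defaults to rep_duration_s * rate_hz (200 at 50 Hz / 4 s);
    ``joints`` None means every joint present in the demonstrations."""

    n: Optional[int] = None
    joints: Optional[List[str]] = None
    min_reps: int = 10

    def __post_init__(self) -> None:
        if self.n is not None and self.n < 2:
            raise ValueError("n must be >= 2")
        if self.min_reps < 2:
            raise ValueError("min_reps must be >= 2")


@dataclass
class DetectorConfig:
    """``k``: allowed deviation in sigma units before an error is flagged.
    ``sigma_floor`` (meters) substitutes for zero-variance columns when
    converting errors to sigma units; 0 disables the floor."""

    k: float = 2.0
    sigma_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.sigma_floor < 0:
            raise ValueError("sigma_floor must be >= 0")


def resample_rep(joint_traj, n: int) -> np.ndarray:
    """Linearly interpolate a trajectory of 3-vectors onto ``n`` equally
    spaced points spanning the repetition; returns a 3 x n matrix."""
    traj = np.asarray(joint_traj, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 3:
        raise ValueError("joint_traj must be a sequence of 3-vectors")
    if traj.shape[0] < 2:
        raise ValueError("trajectory must have length >= 2")
    src = np.linspace(0.0, 1.0, traj.shape[0])
    dst = np.linspace(0.0, 1.0, n)
    return np.stack([np.interp(dst, src, traj[:, ax]) for ax in range(3)])


def split_reps(rec: Recording, boundaries=None) -> List[Recording]:
    """Slice a recording into single-repetition recordings using its
    ground-truth boundaries (or explicit ``boundaries``)."""
    bounds = boundaries if boundaries is not None else rec.rep_boundaries
    if not bounds:
        raise SchemaError("recording has no rep boundaries to split on")
    reps = []
    for a, b in bounds:
        reps.append(
            Recording(
                frames=rec.frames[a:b],
                rate_hz=rec.rate_hz,
                subject_id=rec.subject_id,
                exercise=rec.exercise,
                break_condition=rec.break_condition,
                labels=rec.labels[a:b] if rec.labels is not None else None,
            )
        )
    return reps


def build_model(
    reps: Sequence[Recording],
    cfg: Optional[TrainingConfig] = None,
    exercise: Optional[str] = None,
    rep_duration_s: float = 4.0,
) -> MovementModel:
    """Learn M and S per joint from expert repetitions.

    Each element of ``reps`` is a recording restricted to the frames of
    one repetition.  M is the elementwise mean, S the elementwise sample
    standard deviation (ddof=1) of the resampled demonstrations.
    """
    cfg = cfg or TrainingConfig()
    if len(reps) < cfg.min_reps:
        raise ValueError(
            f"need at least {cfg.min_reps} demonstrations, got {len(reps)}"
        )
    rate_hz = reps[0].rate_hz
    n = cfg.n if cfg.n is not None else round(rep_duration_s * rate_hz)
    joints = cfg.joints
    if joints is None:
        joints = reps[0].joint_names()
    for r in reps:
        missing = set(joints) - set(r.joint_names())
        if missing:
            raise SchemaError(f"demonstration missing joints {sorted(missing)}")
    M: Dict[str, np.ndarray] = {}
    S: Dict[str, np.ndarray] = {}
    zero_var = []
    for j in joints:
        stack = np.stack([resample_rep(r.joint(j), n) for r in reps])  # (R,3,n)
        M[j] = stack.mean(axis=0)
        S[j] = stack.std(axis=0, ddof=1)
        if np.any(S[j] == 0):
            zero_var.append(j)
    if zero_var:
        warnings.warn(
            f"zero-variance columns in S for joints {zero_var}; any deviation "
            "there will be flagged as an error",
            stacklevel=2,
        )
    model = MovementModel(
        exercise=exercise or (reps[0].exercise or "unknown"),
        joints=list(joints),
        n=n,
        M=M,
        S=S,
        rep_duration_s=rep_duration_s,
        rate_hz=rate_hz,
    )
    model.validate()
    return model


def map_index(t_elapsed_ms: float, model: MovementModel) -> int:
    """Column index for the elapsed time since REP_STARTED.

    ``i = round(t / rep_duration * (n - 1))`` with round-half-up, clamped
    to [0, n-1].
    """
    if t_elapsed_ms < 0:
        raise ValueError("elapsed time must be >= 0")
    x = t_elapsed_ms / model.rep_duration_ms * (model.n - 1)
    i = int(np.floor(x + 0.5))  # round-half-up
    return min(max(i, 0), model.n - 1)


def detect_error(
    p,
    i: int,
    model: MovementModel,
    joint: str,
    cfg: Optional[DetectorConfig] = None,
) -> np.ndarray:
    """Per-axis error magnitude of position ``p`` against model column ``i``."""
    cfg = cfg or DetectorConfig()
    if not 0 <= i < model.n:
        raise IndexError(f"column index {i} outside [0, {model.n - 1}]")
    p = np.asarray(p, dtype=float)
    Mi = model.M[joint][:, i]
    Si = model.S[joint][:, i]
    d = np.abs(Mi - p)
    # the max() only matters for k < 1, where d - S_i could be negative
    return np.where(d <= cfg.k * Si, 0.0, np.maximum(d - Si, 0.0))


def assess_rep(
    rec: Recording,
    events: Sequence[SegmentationEvent],
    model: MovementModel,
    cfg: Optional[DetectorConfig] = None,
    haptic_cfg: Optional["haptics.HapticConfig"] = None,
) -> List[ErrorAssessment]:
    """Assess every frame of every segmented repetition against the model.

    Streaming-safe: each frame's assessment uses only that frame and the
    repetition start time.  Returns one :class:`ErrorAssessment` per
    (frame, modeled joint); empty when no (REP_STARTED, REP_DONE) pair
    exists in ``events``.
    """
    cfg = cfg or DetectorConfig()
    haptic_cfg = haptic_cfg or haptics.HapticConfig()
    pairs = pairs_from_events(events)
    if not pairs:
        return []
    missing = set(model.joints) - set(rec.joint_names())
    if missing:
        raise SchemaError(f"recording missing modeled joints {sorted(missing)}")
    t_ms = rec.times_ms()
    out: List[ErrorAssessment] = []
    for start, end in pairs:
        frames = range(start, min(end, rec.n_frames))
        idx = [map_index(float(t_ms[f] - t_ms[start]), model) for f in frames]
        for joint in model.joints:
            P = rec.joint(joint)
            Mj = model.M[joint][:, idx].T  # (F,3)
            Sj = model.S[joint][:, idx].T
            pj = P[list(frames)]
            d = np.abs(Mj - pj)
            e = np.where(d <= cfg.k * Sj, 0.0, np.maximum(d - Sj, 0.0))
            e_dir = np.where(pj >= Mj, e, -e)
            S_eff = np.where(Sj > 0, Sj, cfg.sigma_floor)
            if cfg.sigma_floor == 0 and np.any(Sj == 0):
                raise ValueError(
                    f"zero-variance column for joint {joint!r} with sigma_floor "
                    "disabled; set DetectorConfig.sigma_floor > 0"
                )
            e_int = e_dir / S_eff
            h = haptics.haptic_power(e_int, haptic_cfg.f_skill)
            for row, f in enumerate(frames):
                out.append(
                    ErrorAssessment(
                        joint=joint,
                        frame_index=int(f),
                        e=e[row],
                        e_direction=e_dir[row],
                        e_intensity=e_int[row],
                        h_power=h[row],
                        direction_bin=haptics.bin_direction(
                            e_dir[row], haptic_cfg.dominance_fraction
                        ),
                    )
                )
    return out
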