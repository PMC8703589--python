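"""Map joint errors to direction-binned, skill-scaled electrotactile power.

The sign of the deviation locates the error (the joint drifted toward
+axis or -axis); its size in sigma units sets the stimulation power.  The
per-axis power is ``|e_intensity| / f_skill`` capped at 1 — ``f_skill``
(sigma units) tunes sensitivity to the user: larger for patients (gentler
feedback), smaller for athletes.  Power is computed on magnitudes; the
sign is routed exclusively into the direction bin, so power always lies
in [0, 1].

Direction vocabulary: +x right / -x left, +y top / -y bottom, +z front /
-z back; compound labels are ordered front/back, left/right, top/bottom
(e.g. "front-left").  Feedback channels are looked up per (joint,
direction): stimulation is placed on the side the body part drifted
toward, pushing the user back (an elbow drifting outward is stimulated on
the outside of the elbow).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .types import ErrorAssessment, JOINT_VOCABULARY

__all__ = [
    "HapticConfig",
    "HapticCommand",
    "error_direction",
    "error_intensity",
    "haptic_power",
    "bin_direction",
    "default_channel_map",
    "emit_commands",
]

#: Axis -> (positive label, negative label), in canonical compound order
#: front/back first, then left/right, then top/bottom.
_AXIS_LABELS = (
    (2, "front", "back"),
    (0, "right", "left"),
    (1, "top", "bottom"),
)

N_CHANNELS = 80


@dataclass
class HapticConfig:
    f_skill: float = 4.0
    dominance_fraction: float = 0.5
    channel_map: Optional[dict] = None
    power_mode: str = "max"  # "max" or "l2" aggregation over axes

    def __post_init__(self) -> None:
        if self.f_skill <= 0:
            raise ValueError("f_skill must be > 0")
        if not 0 < self.dominance_fraction <= 1:
            raise ValueError("dominance_fraction must be in (0, 1]")
        if self.power_mode not in ("max", "l2"):
            raise ValueError("power_mode must be 'max' or 'l2'")


@dataclass
class HapticCommand:
    channels: List[int]
    power: float
    frame_index: int
    joint: str
    direction: str

    def validate(self) -> None:
        if not self.channels:
            raise ValueError("command must address at least one channel")
        if not 0 <= self.power <= 1:
            raise ValueError("power must lie in [0, 1]")
        if any(not 1 <= c <= N_CHANNELS for c in self.channels):
            raise ValueError(f"channel ids must lie in [1, {N_CHANNELS}]")


def error_direction(e, p, M_i) -> np.ndarray:
    """Sign the error per axis: +e where p >= M_i, -e where p < M_i."""
    e = np.asarray(e, dtype=float)
    p = np.asarray(p, dtype=float)
    M_i = np.asarray(M_i, dtype=float)
    if np.any(e < 0):
        raise ValueError("e must be elementwise >= 0")
    return np.where(p >= M_i, e, -e)


def error_intensity(e_dir, S_i, sigma_floor: float = 0.0) -> np.ndarray:
    """Signed error in sigma units: elementwise e_direction / S_i.

    Zero-variance axes use ``sigma_floor`` instead; with the floor
    disabled they are an error.
    """
    e_dir = np.asarray(e_dir, dtype=float)
    S_i = np.asarray(S_i, dtype=float)
    if np.any(S_i < 0):
        raise ValueError("S_i must be elementwise >= 0")
    S_eff = np.where(S_i > 0, S_i, sigma_floor)
    if np.any(S_eff == 0):
        raise ValueError("S_i contains zeros and sigma_floor is disabled")
    return e_dir / S_eff


def haptic_power(e_int, f_skill: float) -> np.ndarray:
    """Per-axis power in [0, 1]: |e_int| / f_skill, saturating at 1."""
    if f_skill <= 0:
        raise ValueError("f_skill must be > 0")
    a = np.abs(np.asarray(e_int, dtype=float))
    return np.where(a <= f_skill, a / f_skill, 1.0)


def bin_direction(e_dir, dominance_fraction: float = 0.5) -> str:
    """Quantize a signed error vector to a direction label.

    An axis is active when its magnitude is at least
    ``dominance_fraction`` of the largest axis magnitude; active axes
    compose the label in canonical order.  The zero vector maps to
    ``"none"``.
    """
    v = np.asarray(e_dir, dtype=float)
    m = np.abs(v)
    mx = m.max()
    if mx == 0:
        return "none"
    parts = []
    for axis, pos, neg in _AXIS_LABELS:
        if m[axis] >= dominance_fraction * mx and m[axis] > 0:
            parts.append(pos if v[axis] > 0 else neg)
    return "-".join(parts)


def default_channel_map() -> dict:
    """A documented, plausible 80-channel layout.

    Each canonical joint gets four dedicated contact sites (front, back,
    left, right patches, channel ids assigned sequentially); top/bottom
    reuse the front+back / left+right pairs as a ring above/below the
    joint.  This fixture makes every (joint, direction) resolvable; it is
    this package's own layout and claims no hardware fidelity.
    """
    cmap: dict = {}
    cid = 1
    for joint in JOINT_VOCABULARY:
        front, back, left, right = cid, cid + 1, cid + 2, cid + 3
        cid += 4
        if cid > N_CHANNELS + 1:
            # wrap: later joints share the last channel bank
            cid -= 4
            front, back, left, right = cid - 4, cid - 3, cid - 2, cid - 1
        cmap[joint] = {
            "front": [front],
            "back": [back],
            "left": [left],
            "right": [right],
            "top": [front, back],
            "bottom": [left, right],
            "default": [front, back, left, right],
        }
    return cmap


def _lookup_channels(cmap: dict, joint: str, direction: str) -> List[int]:
    entry = cmap.get(joint)
    if entry is None:
        entry = cmap.get("default")
        if entry is None:
            raise KeyError(f"no channel-map entry (or fallback) for joint {joint!r}")
    if direction in entry:
        return list(entry[direction])
    parts = direction.split("-")
    if all(p in entry for p in parts):
        out: List[int] = []
        for p in parts:
            out.extend(c for c in entry[p] if c not in out)
        return out
    if "default" in entry:
        return list(entry["default"])
    raise KeyError(
        f"channel map has no entry for (joint={joint!r}, direction={direction!r}) "
        "and no fallback"
    )


def emit_commands(
    assessments: Sequence[ErrorAssessment],
    cfg: Optional[HapticConfig] = None,
) -> List[HapticCommand]:
    """One command per (frame, joint) assessment with nonzero power."""
    cfg = cfg or HapticConfig()
    cmap = cfg.channel_map if cfg.channel_map is not None else default_channel_map()
    out: List[HapticCommand] = []
    for a in assessments:
        if cfg.power_mode == "max":
            power = float(np.max(a.h_power))
        else:
            power = float(min(np.linalg.norm(a.h_power), 1.0))
        if power <= 0:
            continue
        cmd = HapticCommand(
            channels=_lookup_channels(cmap, a.joint, a.direction_bin),
            power=power,
            frame_index=a.frame_index,
            joint=a.joint,
            direction=a.direction_bin,
        )
        cmd.validate()
        out.append(cmd)
    return out
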