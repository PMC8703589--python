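"""Repetition segmentation from gyroscope magnitudes.

A thresholded state machine over one node's (denoised) gyroscope stream
detects the starting pose, repetition start and repetition end:

* stationary:  ``|g_i| < G_limit`` on every axis;
* moving:      ``sum_i |g_i| > 3 * G_limit``.

Both inequalities are strict.  The machine waits for ``min_hold_frames``
consecutive stationary frames (a 100 ms debounce at the defaults) before
declaring a pose or a repetition end; if per-frame classifier labels are
supplied they gate only the STARTING_POSE transition (majority label over
the hold window must be a ``*_POSE`` label).

Events are indexed at the physically meaningful boundary: STARTING_POSE
and REP_DONE at the first frame of the stationarity hold, REP_STARTED at
the first non-stationary frame after the preceding hold (the decision is
still made online, once the moving predicate confirms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .preprocess import moving_average
from .types import Recording, SchemaError

__all__ = [
    "EventKind",
    "SegmentationEvent",
    "SegmenterConfig",
    "SOURCE_NODE_BY_EXERCISE",
    "is_stationary",
    "is_moving",
    "segment",
    "pairs_from_events",
    "events_from_boundaries",
    "segmentation_accuracy",
]

#: Best segmentation source per exercise: leg exercises use the right
#: thigh gyroscope, push-ups the right upper arm.
SOURCE_NODE_BY_EXERCISE = {
    "squat": "right_thigh",
    "lunge": "right_thigh",
    "pushup": "right_upper_arm",
}


class EventKind(str, Enum):
    STARTING_POSE = "STARTING_POSE"
    REP_STARTED = "REP_STARTED"
    REP_DONE = "REP_DONE"


@dataclass
class SegmentationEvent:
    kind: EventKind
    frame_index: int


@dataclass
class SegmenterConfig:
    """Tuned defaults: ``g_limit`` 8 deg/s and an 8-sample denoise window
    (160 ms at 50 Hz) gave the best boundary recovery in the source study."""

    g_limit: float = 8.0
    denoise_window: int = 8
    source_node: str = "right_thigh"
    min_hold_frames: int = 5

    def __post_init__(self) -> None:
        if self.g_limit <= 0:
            raise ValueError("g_limit must be > 0")
        if self.denoise_window < 1:
            raise ValueError("denoise_window must be >= 1")
        if self.min_hold_frames < 1:
            raise ValueError("min_hold_frames must be >= 1")


def is_stationary(g, g_limit: float) -> bool:
    """All gyroscope axes strictly inside the threshold: |g_i| < G_limit."""
    g = np.asarray(g, dtype=float)
    return bool(np.all(np.abs(g) < g_limit))


def is_moving(g, g_limit: float) -> bool:
    """Summed absolute rate strictly above 3 * G_limit."""
    g = np.asarray(g, dtype=float)
    return bool(np.sum(np.abs(g)) > 3.0 * g_limit)


def _majority_is_pose(labels: Sequence[str], lo: int, hi: int) -> bool:
    window = [labels[i] for i in range(lo, hi)]
    n_pose = sum(1 for l in window if l.endswith("_POSE"))
    return n_pose * 2 > len(window)


def segment(
    rec: Recording,
    config: Optional[SegmenterConfig] = None,
    pose_labels: Optional[Sequence[str]] = None,
) -> List[SegmentationEvent]:
    """Run the segmentation state machine over one recording.

    ``pose_labels`` (per-frame classifier output or ground truth) are
    optional; when given they must have one label per frame.
    """
    config = config or SegmenterConfig()
    g = rec.gyro(config.source_node)  # raises SchemaError if missing
    gf = moving_average(g, config.denoise_window)
    if pose_labels is not None and len(pose_labels) != rec.n_frames:
        raise SchemaError("pose_labels length must equal number of frames")

    events: List[SegmentationEvent] = []
    state = "IDLE"
    hold = 0  # length of current consecutive stationary run
    last_stationary = -1  # index of the most recent stationary frame
    for f in range(rec.n_frames):
        stat = is_stationary(gf[f], config.g_limit)
        if stat:
            hold += 1
            last_stationary = f
        else:
            hold = 0

        if state == "IDLE":
            if hold >= config.min_hold_frames:
                start = f - config.min_hold_frames + 1
                if pose_labels is None or _majority_is_pose(
                    pose_labels, start, f + 1
                ):
                    events.append(SegmentationEvent(EventKind.STARTING_POSE, start))
                    state = "POSE"
        elif state == "POSE":
            if is_moving(gf[f], config.g_limit):
                onset = last_stationary + 1 if last_stationary >= 0 else f
                events.append(SegmentationEvent(EventKind.REP_STARTED, min(onset, f)))
                state = "REP"
                hold = 0
        elif state == "REP":
            if hold >= config.min_hold_frames:
                events.append(
                    SegmentationEvent(
                        EventKind.REP_DONE, f - config.min_hold_frames + 1
                    )
                )
                state = "POSE"  # REP_DONE doubles as the next starting pose
    return events


def pairs_from_events(
    events: Sequence[SegmentationEvent],
) -> List[Tuple[int, int]]:
    """(REP_STARTED, REP_DONE) frame-index pairs, in order; a trailing
    unmatched REP_STARTED is dropped."""
    pairs = []
    start: Optional[int] = None
    for ev in events:
        if ev.kind == EventKind.REP_STARTED:
            start = ev.frame_index
        elif ev.kind == EventKind.REP_DONE and start is not None:
            pairs.append((start, ev.frame_index))
            start = None
    return pairs


def events_from_boundaries(
    boundaries: Sequence[Tuple[int, int]],
) -> List[SegmentationEvent]:
    """Synthesize an event stream from ground-truth rep boundaries."""
    events: List[SegmentationEvent] = []
    if boundaries:
        events.append(
            SegmentationEvent(EventKind.STARTING_POSE, max(boundaries[0][0] - 1, 0))
        )
    for a, b in boundaries:
        events.append(SegmentationEvent(EventKind.REP_STARTED, a))
        events.append(SegmentationEvent(EventKind.REP_DONE, b))
    return events


def segmentation_accuracy(
    detected,
    truth: Sequence[Tuple[int, int]],
    tol_ms: float,
    rate_hz: float = 50.0,
) -> float:
    """Percent of ground-truth reps matched one-to-one by a detected pair.

    ``detected`` may be an event list or (start, end) pairs.  A match
    requires both endpoints within ``tol_ms``; matching is greedy and
    in-order.
    """
    if tol_ms < 0:
        raise ValueError("tol_ms must be >= 0")
    if detected and isinstance(detected[0], SegmentationEvent):
        pairs = pairs_from_events(detected)
    else:
        pairs = [tuple(p) for p in detected]
    truth = [tuple(b) for b in truth]
    if not truth:
        return 100.0
    frame_ms = 1000.0 / rate_hz
    tol_frames = tol_ms / frame_ms
    matched = 0
    j = 0
    for a, b in truth:
        while j < len(pairs):
            da, db = pairs[j]
            if abs(da - a) <= tol_frames and abs(db - b) <= tol_frames:
                matched += 1
                j += 1
                break
            if da < a - tol_frames:
                j += 1  # detected pair starts too early for any later rep
                continue
            break  # detected pair belongs to a later rep
    return 100.0 * matched / len(truth)
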