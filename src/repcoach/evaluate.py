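"""Reporting surfaces: confusion report, segmentation table, error maps.

All percentages are rounded to two decimals with round-half-up, and every
report carries the raw counts it was computed from, so each ratio can be
recomputed independently.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import CVResult, metrics_from_confusion
from .types import ErrorAssessment, IntegrityError, MovementModel

__all__ = [
    "round_half_up",
    "confusion_report",
    "segmentation_table",
    "error_map",
]

BREAK_ORDER = ("long", "short", "none")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (so 99.385 -> 99.39, not banker's rounding)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def confusion_report(
    cv: CVResult,
    out_dir: Optional[str] = None,
    plots: bool = False,
) -> dict:
    """Raw-count and row-normalized confusion matrices plus metrics.

    The metrics are recomputed from the counts and cross-checked against
    the ``CVResult`` fields to 1e-12; disagreement raises
    :class:`IntegrityError`.
    """
    cm = np.asarray(cv.confusion, dtype=float)
    recomputed = metrics_from_confusion(cm)
    stored = {
        "accuracy": cv.accuracy,
        "macro_precision": cv.macro_precision,
        "macro_recall": cv.macro_recall,
        "macro_f1": cv.macro_f1,
    }
    for key, val in recomputed.items():
        if abs(val - stored[key]) > 1e-12:
            raise IntegrityError(
                f"CVResult.{key}={stored[key]!r} disagrees with value "
                f"recomputed from counts ({val!r})"
            )
    row = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        normalized = np.where(row > 0, cm / row, 0.0)
    report = {
        "labels": list(cv.labels),
        "counts": cm.astype(int).tolist(),
        "row_normalized": normalized.tolist(),
        "metrics": {k: recomputed[k] for k in recomputed},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import json

        with open(out / "confusion.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
        if plots:
            _plot_heatmap(
                normalized, cv.labels, out / "confusion.png", "Row-normalized confusion"
            )
    return report


def _plot_heatmap(matrix, labels, path, title) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix, cmap="Blues", vmin=0, vmax=max(1.0, np.max(matrix)))
    ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right")
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(title)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def segmentation_table(
    runs: Sequence[Tuple[str, str, float]],
) -> pd.DataFrame:
    """Exercise x break-condition accuracy table with an unweighted
    average row, all entries rounded half-up to two decimals.

    ``runs``: (exercise, break_condition, accuracy-percent) triples.
    """
    cells: Dict[str, Dict[str, List[float]]] = {}
    for exercise, brk, acc in runs:
        if not 0 <= acc <= 100:
            raise ValueError(f"accuracy {acc} outside [0, 100]")
        cells.setdefault(exercise, {}).setdefault(brk, []).append(acc)
    exercises = list(dict.fromkeys(ex for ex, _, _ in runs))
    breaks = [b for b in BREAK_ORDER if any(b in v for v in cells.values())]
    extra = [b for _, b, _ in runs if b not in breaks]
    breaks += list(dict.fromkeys(extra))
    data = {}
    for b in breaks:
        col = []
        for ex in exercises:
            vals = cells.get(ex, {}).get(b)
            col.append(round_half_up(float(np.mean(vals))) if vals else np.nan)
        avg = round_half_up(float(np.mean([v for v in col if not np.isnan(v)])))
        data[b] = col + [avg]
    return pd.DataFrame(data, index=exercises + ["Average"])


def error_map(
    assessments: Sequence[ErrorAssessment],
    model: Optional[MovementModel] = None,
) -> pd.DataFrame:
    """Per (joint, direction) aggregation of detected execution errors.

    For every joint and flagged direction: the number of flagged frames,
    the flag rate (flagged / assessed frames of that joint) and the mean
    intensity (max-axis |e_intensity| over the flagged frames).  Joints
    with no flags appear once with direction ``"none"`` and flag rate 0.
    """
    if not assessments:
        raise ValueError("assessments must be non-empty")
    totals: Dict[str, int] = {}
    flagged: Dict[Tuple[str, str], List[float]] = {}
    for a in assessments:
        totals[a.joint] = totals.get(a.joint, 0) + 1
        if np.any(a.e > 0):
            flagged.setdefault((a.joint, a.direction_bin), []).append(
                float(np.max(np.abs(a.e_intensity)))
            )
    joints = model.joints if model is not None else sorted(totals)
    rows = []
    for j in joints:
        n = totals.get(j, 0)
        dirs = [d for (jj, d) in flagged if jj == j]
        if not dirs:
            rows.append(
                {"joint": j, "direction": "none", "n_frames": n, "n_flagged": 0,
                 "flag_rate": 0.0, "mean_intensity": 0.0}
            )
            continue
        for d in sorted(dirs):
            vals = flagged[(j, d)]
            rows.append(
                {
                    "joint": j,
                    "direction": d,
                    "n_frames": n,
                    "n_flagged": len(vals),
                    "flag_rate": len(vals) / n,
                    "mean_intensity": float(np.mean(vals)),
                }
            )
    return pd.DataFrame(rows)
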