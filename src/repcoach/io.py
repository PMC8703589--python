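"""Read/write recordings and movement models in stable on-disk formats.

Recording CSV: one row per frame with columns ``t_ms,subject,label``, then
per node ``<node>_acc_{x,y,z}``, ``<node>_gyr_{x,y,z}`` and optionally
``<node>_mag_{x,y,z}`` / ``<node>_quat_{w,x,y,z}``, then per joint
``<joint>_pos_{x,y,z}``.  Additional metadata columns ``exercise``,
``break_cond`` and ``rep`` (per-frame repetition index, -1 outside a rep)
make the round-trip lossless.  JSONL: a leading meta object line followed
by one frame object per line with the same field names, nested.

MovementModel files are JSON objects
``{schema_version, exercise, rate_hz, rep_duration_s, n, joints: {name: {M, S}}}``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .types import (
    NODE_NAMES,
    Frame,
    MovementModel,
    Recording,
    RecordingParseError,
    SchemaError,
    SensorNodeSample,
)

__all__ = ["read_recording", "write_recording", "save_model", "load_model"]

MODEL_SCHEMA_VERSION = "1"

_AXES = ("x", "y", "z")
_QAXES = ("w", "x", "y", "z")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("csv", "jsonl"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    return "jsonl" if path.suffix in (".jsonl", ".ndjson") else "csv"


def _boundaries_to_rep_column(rec: Recording) -> np.ndarray:
    rep = np.full(rec.n_frames, -1, dtype=int)
    if rec.rep_boundaries:
        for k, (a, b) in enumerate(rec.rep_boundaries):
            rep[a:b] = k
    return rep


def _rep_column_to_boundaries(rep: np.ndarray) -> Optional[List[Tuple[int, int]]]:
    ks = sorted(set(int(v) for v in rep if v >= 0))
    if not ks:
        return None
    out = []
    for k in ks:
        idx = np.flatnonzero(rep == k)
        out.append((int(idx[0]), int(idx[-1]) + 1))
    return out


def write_recording(rec: Recording, path, format: Optional[str] = None) -> None:
    """Serialize a recording; refuses to write an empty one."""
    if not rec.frames:
        raise SchemaError("refusing to write a recording with no frames")
    rec.validate()
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(rec, path)
    else:
        _write_jsonl(rec, path)


def _write_csv(rec: Recording, path: Path) -> None:
    joints = rec.joint_names()
    has_mag = {n: rec.frames[0].nodes[n].mag is not None for n in NODE_NAMES}
    has_quat = {n: rec.frames[0].nodes[n].quat is not None for n in NODE_NAMES}
    cols: dict = {
        "t_ms": rec.times_ms(),
        "subject": rec.subject_id,
        "label": rec.labels if rec.labels is not None else "",
        "exercise": rec.exercise if rec.exercise is not None else "",
        "break_cond": rec.break_condition,
        "rep": _boundaries_to_rep_column(rec),
    }
    for n in NODE_NAMES:
        acc = rec.accel(n)
        gyr = rec.gyro(n)
        for i, ax in enumerate(_AXES):
            cols[f"{n}_acc_{ax}"] = acc[:, i]
            cols[f"{n}_gyr_{ax}"] = gyr[:, i]
        if has_mag[n]:
            mag = np.stack([f.nodes[n].mag for f in rec.frames])
            for i, ax in enumerate(_AXES):
                cols[f"{n}_mag_{ax}"] = mag[:, i]
        if has_quat[n]:
            quat = np.stack([f.nodes[n].quat for f in rec.frames])
            for i, ax in enumerate(_QAXES):
                cols[f"{n}_quat_{ax}"] = quat[:, i]
    for j in joints:
        pos = rec.joint(j)
        for i, ax in enumerate(_AXES):
            cols[f"{j}_pos_{ax}"] = pos[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def _frame_to_json(rec: Recording, f: Frame, label: Optional[str]) -> dict:
    obj: dict = {"t_ms": int(f.t_ms)}
    if label is not None:
        obj["label"] = label
    nodes = {}
    for n, s in f.nodes.items():
        d = {"acc": s.accel.tolist(), "gyr": s.gyro.tolist()}
        if s.mag is not None:
            d["mag"] = s.mag.tolist()
        if s.quat is not None:
            d["quat"] = s.quat.tolist()
        nodes[n] = d
    obj["nodes"] = nodes
    obj["joints"] = {j: p.tolist() for j, p in f.joints.items()}
    return obj


def _write_jsonl(rec: Recording, path: Path) -> None:
    meta = {
        "type": "meta",
        "rate_hz": rec.rate_hz,
        "subject": rec.subject_id,
        "exercise": rec.exercise,
        "break_cond": rec.break_condition,
        "rep_boundaries": [list(b) for b in rec.rep_boundaries]
        if rec.rep_boundaries
        else None,
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps(meta) + "\n")
        labels = rec.labels if rec.labels is not None else [None] * rec.n_frames
        for f, lab in zip(rec.frames, labels):
            fh.write(json.dumps(_frame_to_json(rec, f, lab)) + "\n")


def read_recording(path, format: Optional[str] = None) -> Recording:
    """Parse a recording file; validates all invariants on the result."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    rec = _read_csv(path) if fmt == "csv" else _read_jsonl(path)
    rec.validate()
    return rec


_KNOWN_META_COLS = {"t_ms", "subject", "label", "exercise", "break_cond", "rep"}


def _node_of_column(c: str) -> Optional[str]:
    for n in NODE_NAMES:
        for kind, axes in (("acc", _AXES), ("gyr", _AXES), ("mag", _AXES), ("quat", _QAXES)):
            if c in {f"{n}_{kind}_{ax}" for ax in axes}:
                return n
    return None


def _read_csv(path: Path) -> Recording:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise RecordingParseError(f"could not parse CSV {path}: {exc}") from exc
    if "t_ms" not in df.columns:
        raise SchemaError("CSV is missing mandatory column 't_ms'")
    for n in NODE_NAMES:
        for kind in ("acc", "gyr"):
            for ax in _AXES:
                col = f"{n}_{kind}_{ax}"
                if col not in df.columns:
                    raise SchemaError(f"CSV is missing required node column {col!r}")
    joint_names = sorted(
        {
            c[: -len("_pos_x")]
            for c in df.columns
            if c.endswith("_pos_x")
        }
    )
    known = set(_KNOWN_META_COLS)
    for c in df.columns:
        if c in known or _node_of_column(c) is not None:
            continue
        if any(c == f"{j}_pos_{ax}" for j in joint_names for ax in _AXES):
            continue
        warnings.warn(f"ignoring unknown column {c!r} in {path.name}", stacklevel=2)

    numeric_cols = [c for c in df.columns if c.endswith(tuple(f"_{a}" for a in _QAXES))]
    numeric_cols = ["t_ms"] + [c for c in numeric_cols if _node_of_column(c) or c.endswith("_pos_x") or c.endswith("_pos_y") or c.endswith("_pos_z")]
    for c in numeric_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna() if df[c].dtype == object else vals.isna()
        if bad.any():
            # +2: header line plus 1-based file numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise RecordingParseError(
                f"malformed value in column {c!r} at line {line} of {path.name}"
            )
        df[c] = vals

    has_mag = {n: f"{n}_mag_x" in df.columns for n in NODE_NAMES}
    has_quat = {n: f"{n}_quat_w" in df.columns for n in NODE_NAMES}
    frames: List[Frame] = []
    for idx in range(len(df)):
        row = df.iloc[idx]
        nodes = {}
        for n in NODE_NAMES:
            nodes[n] = SensorNodeSample(
                accel=[row[f"{n}_acc_{ax}"] for ax in _AXES],
                gyro=[row[f"{n}_gyr_{ax}"] for ax in _AXES],
                mag=[row[f"{n}_mag_{ax}"] for ax in _AXES] if has_mag[n] else None,
                quat=[row[f"{n}_quat_{ax}"] for ax in _QAXES] if has_quat[n] else None,
            )
        joints = {
            j: [row[f"{j}_pos_{ax}"] for ax in _AXES] for j in joint_names
        }
        frames.append(Frame(t_ms=int(row["t_ms"]), nodes=nodes, joints=joints))

    labels = None
    if "label" in df.columns and df["label"].notna().any():
        labels = [str(v) for v in df["label"].fillna("")]
        if all(v == "" for v in labels):
            labels = None
    subject = str(df["subject"].iloc[0]) if "subject" in df.columns else ""
    exercise = None
    if "exercise" in df.columns:
        v = df["exercise"].iloc[0]
        exercise = None if (pd.isna(v) or str(v) == "") else str(v)
    break_cond = str(df["break_cond"].iloc[0]) if "break_cond" in df.columns else "n/a"
    boundaries = (
        _rep_column_to_boundaries(df["rep"].to_numpy())
        if "rep" in df.columns
        else None
    )
    t = df["t_ms"].to_numpy()
    rate = 50.0 if len(t) < 2 else round(1000.0 / float(np.median(np.diff(t))), 6)
    return Recording(
        frames=frames,
        rate_hz=rate,
        subject_id=subject,
        exercise=exercise,
        break_condition=break_cond,
        labels=labels,
        rep_boundaries=boundaries,
    )


def _read_jsonl(path: Path) -> Recording:
    frames: List[Frame] = []
    labels: List[Optional[str]] = []
    meta: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise RecordingParseError(
                    f"malformed JSON at line {lineno} of {path.name}: {exc}"
                ) from exc
            if obj.get("type") == "meta":
                meta = obj
                continue
            try:
                nodes = {
                    n: SensorNodeSample(
                        accel=d["acc"],
                        gyro=d["gyr"],
                        mag=d.get("mag"),
                        quat=d.get("quat"),
                    )
                    for n, d in obj["nodes"].items()
                }
                frames.append(
                    Frame(t_ms=obj["t_ms"], nodes=nodes, joints=obj.get("joints", {}))
                )
            except (KeyError, TypeError) as exc:
                raise RecordingParseError(
                    f"malformed frame at line {lineno} of {path.name}: {exc}"
                ) from exc
            labels.append(obj.get("label"))
    use_labels = [l for l in labels] if any(l is not None for l in labels) else None
    boundaries = meta.get("rep_boundaries")
    return Recording(
        frames=frames,
        rate_hz=float(meta.get("rate_hz", 50.0)),
        subject_id=str(meta.get("subject", "")),
        exercise=meta.get("exercise"),
        break_condition=meta.get("break_cond", "n/a"),
        labels=[str(l) for l in use_labels] if use_labels else None,
        rep_boundaries=[tuple(b) for b in boundaries] if boundaries else None,
    )


def save_model(model: MovementModel, path) -> None:
    """Write a movement model as versioned JSON (lossless for M and S)."""
    model.validate()
    obj = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "exercise": model.exercise,
        "rate_hz": model.rate_hz,
        "rep_duration_s": model.rep_duration_s,
        "n": model.n,
        "joints": {
            j: {"M": model.M[j].tolist(), "S": model.S[j].tolist()}
            for j in model.joints
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh)


def load_model(path) -> MovementModel:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    version = obj.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise SchemaError(
            f"model schema version mismatch: file has {version!r}, "
            f"this build reads {MODEL_SCHEMA_VERSION!r}"
        )
    joints = list(obj["joints"])
    model = MovementModel(
        exercise=obj["exercise"],
        joints=joints,
        n=int(obj["n"]),
        M={j: np.asarray(obj["joints"][j]["M"], dtype=float) for j in joints},
        S={j: np.asarray(obj["joints"][j]["S"], dtype=float) for j in joints},
        rep_duration_s=float(obj["rep_duration_s"]),
        rate_hz=float(obj["rate_hz"]),
    )
    model.validate()
    return model
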