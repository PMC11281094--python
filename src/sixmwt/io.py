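"""Readers and writers for traces, subject records, and result documents.

Trace files are plain CSV with a header row ``t,x,y,z`` — time in seconds
and acceleration in m/s² (pass ``unit="g"`` to convert on read).  Subject
records, configurations and analysis results travel as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    G_STANDARD,
    AccelTrace,
    AnalysisConfig,
    GaitSummary,
    Gender,
    SegmentParams,
    SubjectRecord,
    WalkSegment,
)

PathLike = Union[str, Path]

_TIME_ALIASES = {"t", "time", "timestamp"}


def read_trace(
    path: PathLike,
    unit: str = "m/s2",
    fs: Optional[float] = None,
    sensor_id: Optional[str] = None,
) -> AccelTrace:
    """Read a CSV acceleration trace and validate it.

    Parameters
    ----------
    unit
        ``"m/s2"`` (stored as-is) or ``"g"`` (multiplied by 9.80665).
    fs
        Declared sampling rate; when given, an inferred rate deviating by
        more than 5% is a hard error.  When omitted, fs is inferred from
        the median time spacing.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    time_col = next((c for c in df.columns if c in _TIME_ALIASES), None)
    if time_col is None:
        raise ValueError(f"{path}: no time column (expected one of {sorted(_TIME_ALIASES)})")
    for c in ("x", "y", "z"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    t = df[time_col].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples to infer fs")
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        # +2: +1 for the diff offset, +1 for the header row of the file
        raise ValueError(f"{path}: time not strictly increasing at data row {bad[0] + 2}")
    fs_inferred = 1.0 / float(np.median(dt))
    if fs is not None and abs(fs_inferred - fs) > 0.05 * fs:
        raise ValueError(
            f"{path}: inferred sampling rate {fs_inferred:.3f} Hz deviates more "
            f"than 5% from declared {fs} Hz"
        )
    scale = G_STANDARD if unit == "g" else 1.0
    if unit not in ("g", "m/s2"):
        raise ValueError(f"unknown unit {unit!r} (expected 'm/s2' or 'g')")
    return AccelTrace(
        t=t,
        x=df["x"].to_numpy(dtype=float) * scale,
        y=df["y"].to_numpy(dtype=float) * scale,
        z=df["z"].to_numpy(dtype=float) * scale,
        fs=fs if fs is not None else fs_inferred,
        sensor_id=sensor_id if sensor_id is not None else path.stem,
        unit="m/s2",
    )


def write_trace(trace: AccelTrace, path: PathLike) -> None:
    """Write a trace as ``t,x,y,z`` CSV (full float precision, round-trip exact)."""
    df = pd.DataFrame({"t": trace.t, "x": trace.x, "y": trace.y, "z": trace.z})
    df.to_csv(path, index=False, float_format="%.17g")


def write_segments(segments: Sequence[WalkSegment], path: PathLike) -> None:
    """Write a segment report as tab-separated ``label  start  end  complete``."""
    rows = [
        {"label": s.label.value, "start": s.start, "end": s.end, "complete": s.complete}
        for s in segments
    ]
    pd.DataFrame(rows, columns=["label", "start", "end", "complete"]).to_csv(
        path, sep="\t", index=False
    )


def read_subject(path: PathLike) -> SubjectRecord:
    """Read a SubjectRecord from JSON."""
    with open(path) as fh:
        data = json.load(fh)
    return subject_from_dict(data)


def subject_from_dict(data: dict[str, Any]) -> SubjectRecord:
    known = {f.name for f in dataclasses.fields(SubjectRecord)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown subject fields: {sorted(unknown)}")
    if "subject_id" not in data:
        raise ValueError("subject record requires a subject_id")
    return SubjectRecord(**data)


def write_subject(subject: SubjectRecord, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(_plain(dataclasses.asdict(subject)), fh, indent=2)
        fh.write("\n")


def _plain(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays and enums to JSON-clean types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, Gender):
        return int(obj)
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_results(
    summary: GaitSummary,
    subject: Optional[SubjectRecord],
    scores: Optional[dict[str, Any]],
    path: PathLike,
    config: Optional[AnalysisConfig] = None,
    units: Optional[dict[str, str]] = None,
) -> None:
    """Serialize a full analysis (gait summary + subject + scores + config) as JSON.

    The document is machine-readable and round-trips losslessly through
    :func:`read_results`; an empty per-segment table serializes as ``[]``.
    """
    doc: dict[str, Any] = {
        "format": "sixmwt-results",
        "version": 1,
        "units": units or {
            "sl": "m/step", "sc": "step/s", "gv": "m/s",
            "six_mwd": "m", "six_mwee": "kcal/h",
        },
        "gait": _plain(dataclasses.asdict(summary)),
        "subject": _plain(dataclasses.asdict(subject)) if subject is not None else None,
        "scores": _plain(scores) if scores is not None else None,
        "config": _plain(dataclasses.asdict(config)) if config is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_results(path: PathLike) -> dict[str, Any]:
    """Read a results document back; reconstructs typed objects where possible."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "sixmwt-results":
        raise ValueError(f"{path}: not a sixmwt results document")
    gait = dict(doc["gait"])
    gait["per_segment"] = [SegmentParams(**row) for row in gait.get("per_segment", [])]
    doc["gait"] = GaitSummary(**gait)
    if doc.get("subject") is not None:
        doc["subject"] = subject_from_dict(doc["subject"])
    if doc.get("config") is not None:
        cfg = dict(doc["config"])
        if isinstance(cfg.get("cadence_band"), list):
            cfg["cadence_band"] = tuple(cfg["cadence_band"])
        doc["config"] = AnalysisConfig(**cfg)
    return doc
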