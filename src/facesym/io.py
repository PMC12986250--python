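"""Trajectory, descriptor-table and report I/O.

Trajectory CSV: columns ``frame,marker_id,x,y`` (pixels). Eye centroids
travel in the same file under the reserved marker ids ``eyeL``/``eyeR``.
Recording metadata (id, exercise, fps, optional S/AS label) lives in a
JSON sidecar so trajectory files stay label-agnostic.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .model import (
    EYE_LEFT_ID,
    EYE_RIGHT_ID,
    EyeTrackPair,
    Exercise,
    MarkerTrack,
    Recording,
    RaterPanel,
    SymmetryLabel,
    ValidationError,
)

TRAJECTORY_COLUMNS = ["frame", "marker_id", "x", "y"]


def _track_from_rows(marker_id: str, frames: np.ndarray, xy: np.ndarray) -> MarkerTrack:
    """Densify observed (frame, xy) rows into a contiguous-span track."""
    lo, hi = int(frames.min()), int(frames.max())
    span = np.arange(lo, hi + 1)
    dense_xy = np.full((span.size, 2), np.nan)
    valid = np.zeros(span.size, dtype=bool)
    idx = frames - lo
    dense_xy[idx] = xy
    valid[idx] = True
    return MarkerTrack(marker_id, span, dense_xy, valid)


def read_trajectories(path: str | Path) -> dict[str, MarkerTrack]:
    """Parse a trajectory CSV into per-marker tracks keyed by marker id."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"marker_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"malformed trajectory CSV {path}: {exc}") from exc
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df["frame"].isna().any() or df[["x", "y"]].isna().all(axis=1).any():
        bad = int(df.index[df[["frame", "x", "y"]].isna().any(axis=1)][0]) + 2
        raise ValidationError(f"{path}: malformed row at line {bad}")
    dup = df.duplicated(subset=["frame", "marker_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate entry for frame {int(row['frame'])}, "
            f"marker {row['marker_id']!r}"
        )
    tracks: dict[str, MarkerTrack] = {}
    for mid, grp in df.groupby("marker_id", sort=True):
        grp = grp.sort_values("frame")
        tracks[str(mid)] = _track_from_rows(
            str(mid),
            grp["frame"].to_numpy(dtype=int),
            grp[["x", "y"]].to_numpy(dtype=float),
        )
    return tracks


def read_recording(
    path: str | Path,
    *,
    exercise: Exercise | str | None = None,
    fps: float | None = None,
    label: SymmetryLabel | str | None = None,
    recording_id: str | None = None,
) -> Recording:
    """Load a recording from a trajectory CSV (+ optional JSON sidecar).

    Explicit keyword metadata overrides the sidecar ``<stem>.json`` when
    both are present; exercise and fps must come from one of the two.
    """
    path = Path(path)
    meta: dict[str, Any] = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    exercise = exercise if exercise is not None else meta.get("exercise")
    fps = fps if fps is not None else meta.get("fps")
    label = label if label is not None else meta.get("label")
    recording_id = recording_id or meta.get("recording_id") or path.stem
    if exercise is None or fps is None:
        raise ValidationError(
            f"{path}: exercise and fps required (argument or {sidecar.name})"
        )

    tracks = read_trajectories(path)
    for eye_id in (EYE_LEFT_ID, EYE_RIGHT_ID):
        if eye_id not in tracks:
            raise ValidationError(f"{path}: reserved eye track {eye_id!r} absent")
    left = tracks.pop(EYE_LEFT_ID)
    right = tracks.pop(EYE_RIGHT_ID)
    return Recording(
        recording_id=recording_id,
        exercise=Exercise(exercise),
        fps=float(fps),
        markers=tracks,
        eyes=EyeTrackPair(left, right),
        label=SymmetryLabel(label) if label is not None else None,
    )


def write_trajectories(rec: Recording, path: str | Path, *, write_sidecar: bool = True) -> None:
    """Write a recording back to trajectory CSV (+ metadata sidecar).

    Only valid frames are emitted, so gaps round-trip as gaps.
    """
    path = Path(path)
    rows = []
    all_tracks = dict(rec.markers)
    all_tracks[EYE_LEFT_ID] = rec.eyes.left
    all_tracks[EYE_RIGHT_ID] = rec.eyes.right
    for mid in sorted(all_tracks):
        t = all_tracks[mid]
        for fr, (x, y) in zip(t.frames[t.valid], t.xy[t.valid]):
            rows.append((int(fr), mid, x, y))
    df = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).sort_values(
        ["frame", "marker_id"], kind="stable"
    )
    df.to_csv(path, index=False)
    if write_sidecar:
        meta = {
            "recording_id": rec.recording_id,
            "exercise": rec.exercise.value,
            "fps": rec.fps,
            "label": rec.label.value if rec.label is not None else None,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


DESCRIPTOR_COLUMNS = [
    "recording_id", "feature", "STD", "MAD", "IQR", "dSTD", "dMAD", "dIQR", "label",
]


def write_descriptor_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a descriptor table (one row per recording x feature) as CSV."""
    missing = [c for c in DESCRIPTOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"descriptor table missing columns {missing}")
    table[DESCRIPTOR_COLUMNS].to_csv(path, index=False)


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"recording_id": str, "feature": str, "label": str})
    missing = [c for c in DESCRIPTOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: descriptor table missing columns {missing}")
    return df


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, (Exercise, SymmetryLabel)):
        return obj.value
    return obj


def write_report(report: Any, path: str | Path) -> None:
    """Serialize a result object (dataclass/dict) to pretty-printed JSON."""
    Path(path).write_text(json.dumps(_to_jsonable(report), indent=2))


def read_rater_panel(path: str | Path) -> RaterPanel:
    """Read a rater panel CSV: column ``recording_id`` + one column per rater."""
    df = pd.read_csv(path, dtype=str)
    if "recording_id" not in df.columns:
        raise ValidationError(f"{path}: rater panel needs a 'recording_id' column")
    rater_cols = [c for c in df.columns if c != "recording_id"]
    if df[rater_cols].isna().any().any():
        raise ValidationError(f"{path}: rater panel has missing cells")
    return RaterPanel(
        recording_ids=df["recording_id"].tolist(),
        ratings=df[rater_cols].to_numpy(dtype=object),
    )
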