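"""Domain types for marker-based facial movement analysis.

Coordinates follow the image convention: origin at the top-left corner,
x increasing rightward, y increasing downward, in pixels.  Frame indices
are 0-based integers.  "Left" means image-left (smaller x for an upright
face), not anatomical left; the ``eyeL``/``eyeR`` labels anchor facial
laterality downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np


class FaceSymError(Exception):
    """Base class for all package errors."""


class ValidationError(FaceSymError):
    """Input data violates a structural precondition."""


class InsufficientDataError(FaceSymError):
    """Not enough valid frames/samples to perform an operation."""


class DegenerateGeometryError(FaceSymError):
    """Geometric construction is undefined (e.g. coincident eyes)."""


class DegenerateDataError(FaceSymError):
    """Statistical operation undefined (e.g. zero variance everywhere)."""


class Exercise(str, enum.Enum):
    EYEBROW_RAISING = "eyebrow_raising"
    SMILING = "smiling"


class SymmetryLabel(str, enum.Enum):
    S = "S"
    AS = "AS"


#: Reserved marker ids carrying the eye centroids inside a trajectory table.
EYE_LEFT_ID = "eyeL"
EYE_RIGHT_ID = "eyeR"


@dataclass(frozen=True)
class Point2D:
    """A single image-plane coordinate in pixels."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class MarkerTrack:
    """Trajectory of one marker over a contiguous span of frames.

    ``frames`` covers the full span (strictly increasing, step 1 after
    ingestion); frames where detection failed carry ``valid=False`` and
    NaN coordinates — missing data is flagged, never fabricated.
    """

    marker_id: str
    frames: np.ndarray  # (n,) int
    xy: np.ndarray      # (n, 2) float, NaN where invalid
    valid: np.ndarray   # (n,) bool

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.frames.ndim != 1 or self.xy.shape != (self.frames.size, 2):
            raise ValidationError(
                f"track {self.marker_id!r}: frames/xy shape mismatch"
            )
        if self.valid.shape != self.frames.shape:
            raise ValidationError(f"track {self.marker_id!r}: valid mask shape mismatch")
        if self.frames.size > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValidationError(
                f"track {self.marker_id!r}: frame indices not strictly increasing"
            )
        if np.any(~np.isfinite(self.xy[self.valid])):
            raise ValidationError(
                f"track {self.marker_id!r}: non-finite coordinates on valid frames"
            )

    def __len__(self) -> int:
        return int(self.frames.size)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def copy(self) -> "MarkerTrack":
        return MarkerTrack(
            self.marker_id, self.frames.copy(), self.xy.copy(), self.valid.copy()
        )


@dataclass
class EyeTrackPair:
    """Left/right eye-centroid tracks; left is image-left (smaller x)."""

    left: MarkerTrack
    right: MarkerTrack

    def __post_init__(self) -> None:
        if not np.array_equal(self.left.frames, self.right.frames):
            raise ValidationError("eye tracks must share the same frame range")

    @property
    def frames(self) -> np.ndarray:
        return self.left.frames

    @property
    def both_valid(self) -> np.ndarray:
        return self.left.valid & self.right.valid

    def ipd(self) -> np.ndarray:
        """Per-frame interocular distance in pixels (NaN where either eye missing)."""
        d = np.linalg.norm(self.right.xy - self.left.xy, axis=1)
        d = np.where(self.both_valid, d, np.nan)
        return d

    def copy(self) -> "EyeTrackPair":
        return EyeTrackPair(self.left.copy(), self.right.copy())


@dataclass
class Recording:
    """One exercise execution: marker tracks + eye centroids + metadata."""

    recording_id: str
    exercise: Exercise
    fps: float
    markers: dict[str, MarkerTrack]
    eyes: EyeTrackPair
    label: SymmetryLabel | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        self.exercise = Exercise(self.exercise)
        if self.label is not None:
            self.label = SymmetryLabel(self.label)
        for mid, track in self.markers.items():
            if mid != track.marker_id:
                raise ValidationError(
                    f"marker dict key {mid!r} != track id {track.marker_id!r}"
                )


@dataclass
class RaterPanel:
    """Categorical S/AS ratings from a panel of independent raters."""

    recording_ids: list[str]
    ratings: np.ndarray  # (n_recordings, n_raters) of "S"/"AS" strings

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=object)
        if self.ratings.ndim != 2:
            raise ValidationError("ratings must be a 2D (items x raters) matrix")
        if self.ratings.shape[0] != len(self.recording_ids):
            raise ValidationError("one row of ratings per recording id required")
        if self.ratings.shape[1] < 2:
            raise ValidationError("at least 2 raters required")
        allowed = {SymmetryLabel.S.value, SymmetryLabel.AS.value}
        bad = set(map(str, self.ratings.ravel())) - allowed
        if bad:
            raise ValidationError(f"ratings contain values outside S/AS: {sorted(bad)}")

    @property
    def n_items(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    message: str


#: Default analysis marker pairs per exercise (image-left id, image-right id).
DEFAULT_MARKER_PAIRS: dict[Exercise, tuple[str, str]] = {
    Exercise.EYEBROW_RAISING: ("00", "01"),
    Exercise.SMILING: ("10", "11"),
}


def validate_recording(rec: Recording) -> list[ValidationIssue]:
    """Report structural problems in a recording without modifying it.

    Pure: repeated calls on the same recording return identical reports.
    Checks frame-range consistency across tracks, eye laterality and
    degenerate IPD frames, and presence of the exercise's analysis markers.
    """
    issues: list[ValidationIssue] = []

    ranges = {mid: (t.frames[0], t.frames[-1]) for mid, t in rec.markers.items() if len(t)}
    eye_range = (rec.eyes.frames[0], rec.eyes.frames[-1]) if len(rec.eyes.left) else None
    if eye_range is not None:
        for mid, rng in sorted(ranges.items()):
            if rng != eye_range:
                issues.append(
                    ValidationIssue(
                        "frame_range_mismatch",
                        f"marker {mid!r} spans frames {rng[0]}..{rng[1]} but eyes span "
                        f"{eye_range[0]}..{eye_range[1]}",
                    )
                )

    ipd = rec.eyes.ipd()
    both = rec.eyes.both_valid
    zero_ipd = rec.eyes.frames[both & (np.nan_to_num(ipd, nan=1.0) <= 0.0)]
    for fr in zero_ipd:
        issues.append(ValidationIssue("zero_ipd", f"IPD is zero at frame {int(fr)}"))

    swapped = both & (rec.eyes.left.xy[:, 0] >= rec.eyes.right.xy[:, 0])
    swapped &= np.nan_to_num(ipd, nan=1.0) > 0
    if np.any(swapped):
        n = int(swapped.sum())
        issues.append(
            ValidationIssue(
                "eye_laterality",
                f"left eye is not image-left of right eye on {n} frame(s)",
            )
        )

    pair = DEFAULT_MARKER_PAIRS[rec.exercise]
    for mid in pair:
        if mid not in rec.markers:
            issues.append(
                ValidationIssue(
                    "required_marker_missing",
                    f"required marker {mid!r} missing for exercise "
                    f"{rec.exercise.value!r}",
                )
            )
    return issues
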