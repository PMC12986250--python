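"""Per-frame movement features: VertDist, Ratio and marker-axis distances.

For the homologous marker pair of the active exercise, two features are
computed per frame:

* ``VertDist(t) = |y_i(t) - y_j(t)|`` — absolute vertical (image-y)
  distance between the pair, in pixels.
* ``Ratio(t) = d_L(t) / d_R(t)`` — quotient of the two markers'
  perpendicular distances to the per-frame symmetry axis; 1 indicates
  lateral symmetry.

Left/right is assigned by the image x-coordinate of each marker's median
position (image laterality, recorded in the output for auditability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .geometry import SymmetryAxisSeries, points_line_distances
from .model import (
    DEFAULT_MARKER_PAIRS,
    Exercise,
    InsufficientDataError,
    MarkerTrack,
    Recording,
    ValidationError,
)

logger = logging.getLogger(__name__)

FEATURE_VERTDIST = "VertDist"
FEATURE_RATIO = "Ratio"
FEATURE_DIST_LEFT = "dist_left"
FEATURE_DIST_RIGHT = "dist_right"


@dataclass
class FeatureSeries:
    """A named per-frame scalar series for one recording."""

    recording_id: str
    name: str
    frames: np.ndarray  # (n,) int, increasing (not necessarily contiguous)
    values: np.ndarray  # (n,) float
    meta: dict | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.frames.shape != self.values.shape:
            raise ValidationError(f"{self.name}: frames/values shape mismatch")

    def __len__(self) -> int:
        return int(self.frames.size)


@dataclass(frozen=True)
class MarkerPairSpec:
    """The homologous marker pair analyzed for an exercise."""

    exercise: Exercise
    left_id: str
    right_id: str

    def __post_init__(self) -> None:
        if self.left_id == self.right_id:
            raise ValidationError("marker pair must name two distinct markers")


def select_exercise_markers(
    exercise: Exercise | str,
    overrides: dict[Exercise, tuple[str, str]] | None = None,
) -> MarkerPairSpec:
    """Analysis pair for an exercise: eyebrow raising -> (00, 01), smiling -> (10, 11)."""
    exercise = Exercise(exercise)
    if overrides and exercise in overrides:
        left_id, right_id = overrides[exercise]
    else:
        left_id, right_id = DEFAULT_MARKER_PAIRS[exercise]
    return MarkerPairSpec(exercise, left_id, right_id)


def _common_valid(track_i: MarkerTrack, track_j: MarkerTrack) -> np.ndarray:
    """Sorted frame indices where both tracks are valid."""
    fi = track_i.frames[track_i.valid]
    fj = track_j.frames[track_j.valid]
    return np.intersect1d(fi, fj)


def _values_at(track: MarkerTrack, frames: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(track.frames, frames)
    return track.xy[idx]


def vert_dist(
    track_i: MarkerTrack, track_j: MarkerTrack, recording_id: str = ""
) -> FeatureSeries:
    """Absolute vertical inter-marker distance per common valid frame."""
    frames = _common_valid(track_i, track_j)
    if frames.size == 0:
        raise InsufficientDataError(
            f"tracks {track_i.marker_id!r}/{track_j.marker_id!r} share no valid frames"
        )
    yi = _values_at(track_i, frames)[:, 1]
    yj = _values_at(track_j, frames)[:, 1]
    return FeatureSeries(recording_id, FEATURE_VERTDIST, frames, np.abs(yi - yj))


def _assign_left_right(
    a: MarkerTrack,
    b: MarkerTrack,
    rec: Recording,
    frames: np.ndarray,
    abc: np.ndarray,
) -> tuple[MarkerTrack, MarkerTrack]:
    """Order a homologous pair by facial laterality.

    The "left" member is the one lying (in the median over frames) on the
    same side of the symmetry axis as the left-eye centroid. Anchoring
    laterality to the labeled eye rather than to raw image x keeps the
    assignment — and hence the Ratio — covariant with any rigid motion of
    the whole scene, including large head roll.
    """
    eye_idx = np.searchsorted(rec.eyes.frames, frames)
    eye_xy = rec.eyes.left.xy[eye_idx]

    def signed(points: np.ndarray) -> np.ndarray:
        return abc[:, 0] * points[:, 0] + abc[:, 1] * points[:, 1] + abc[:, 2]

    side = np.sign(signed(eye_xy))
    side[side == 0] = 1.0
    score_a = float(np.median(signed(_values_at(a, frames)) * side))
    score_b = float(np.median(signed(_values_at(b, frames)) * side))
    return (a, b) if score_a >= score_b else (b, a)


def ratio(
    rec: Recording,
    axes: SymmetryAxisSeries,
    pair: MarkerPairSpec,
    orientation: str = "left_over_right",
    degeneracy_floor: float = 1e-6,
) -> tuple[FeatureSeries, FeatureSeries, FeatureSeries]:
    """Lateral-asymmetry ratio of marker-axis distances, plus both distances.

    Returns ``(ratio, dist_left, dist_right)`` on frames where both
    markers and the axis are available. Frames where the denominator
    marker sits within ``degeneracy_floor`` pixels of the axis are
    dropped with a warning rather than producing infinities.
    """
    for mid in (pair.left_id, pair.right_id):
        if mid not in rec.markers:
            raise ValidationError(
                f"recording {rec.recording_id}: marker {mid!r} required for "
                f"exercise {pair.exercise.value!r} is missing"
            )
    track_a, track_b = rec.markers[pair.left_id], rec.markers[pair.right_id]
    frames = _common_valid(track_a, track_b)
    frames = np.intersect1d(frames, axes.frames)
    if frames.size == 0:
        raise InsufficientDataError(
            f"recording {rec.recording_id}: no frame has both markers and an axis"
        )
    axis_idx = np.searchsorted(axes.frames, frames)
    abc = axes.abc[axis_idx]
    left, right = _assign_left_right(track_a, track_b, rec, frames, abc)
    d_left = points_line_distances(_values_at(left, frames), abc)
    d_right = points_line_distances(_values_at(right, frames), abc)

    if orientation == "left_over_right":
        num, den = d_left, d_right
    elif orientation == "right_over_left":
        num, den = d_right, d_left
    else:
        raise ValidationError(f"unknown ratio orientation {orientation!r}")
    ok = den > degeneracy_floor
    if not np.all(ok):
        logger.warning(
            "recording %s: dropping %d frame(s) where the denominator marker "
            "lies on the symmetry axis", rec.recording_id, int((~ok).sum()),
        )
    if not np.any(ok):
        raise InsufficientDataError(
            f"recording {rec.recording_id}: ratio denominator degenerate on all frames"
        )
    meta = {"orientation": orientation, "left_id": left.marker_id,
            "right_id": right.marker_id}
    return (
        FeatureSeries(rec.recording_id, FEATURE_RATIO, frames[ok], num[ok] / den[ok], meta),
        FeatureSeries(rec.recording_id, FEATURE_DIST_LEFT, frames, d_left, meta),
        FeatureSeries(rec.recording_id, FEATURE_DIST_RIGHT, frames, d_right, meta),
    )


def compute_features(
    rec: Recording, axes: SymmetryAxisSeries, config: PipelineConfig | None = None
) -> dict[str, FeatureSeries]:
    """VertDist, Ratio and companion axis-distance series for a recording."""
    config = config or PipelineConfig()
    pair = select_exercise_markers(rec.exercise, config.marker_pair_overrides)
    if pair.left_id not in rec.markers or pair.right_id not in rec.markers:
        raise ValidationError(
            f"recording {rec.recording_id}: analysis markers "
            f"{pair.left_id!r}/{pair.right_id!r} missing"
        )
    vd = vert_dist(rec.markers[pair.left_id], rec.markers[pair.right_id],
                   rec.recording_id)
    rt, dl, dr = ratio(
        rec, axes, pair, config.ratio_orientation, config.ratio_degeneracy_floor
    )
    return {
        FEATURE_VERTDIST: vd,
        FEATURE_RATIO: rt,
        FEATURE_DIST_LEFT: dl,
        FEATURE_DIST_RIGHT: dr,
    }
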