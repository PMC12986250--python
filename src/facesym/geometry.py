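"""Per-frame facial symmetry axis and point-line distances.

The symmetry axis at frame t is the perpendicular bisector of the
segment joining the two eye centroids: the line through the interocular
midpoint, perpendicular to the interocular segment, written in general
form a(t)x + b(t)y + c(t) = 0. It is a geometric, not anatomical,
midline, and is reported even under heavy head roll.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .model import DegenerateGeometryError, EyeTrackPair, InsufficientDataError

logger = logging.getLogger(__name__)

_EPS = 1e-12


class LineCoefficients(NamedTuple):
    """Unit-normalized general-form line coefficients (a² + b² = 1).

    Sign convention: a >= 0, and b > 0 when a == 0, which makes the
    coefficient triple unique per geometric line.
    """

    a: float
    b: float
    c: float


def _normalize_abc(abc: np.ndarray) -> np.ndarray:
    """Unit-normalize rows of (n, 3) line coefficients with the sign convention."""
    norm = np.hypot(abc[:, 0], abc[:, 1])
    if np.any(norm <= _EPS):
        raise DegenerateGeometryError("degenerate line: a and b both (near) zero")
    out = abc / norm[:, None]
    flip = (out[:, 0] < 0) | ((out[:, 0] == 0) & (out[:, 1] < 0))
    out[flip] *= -1.0
    # squash -0.0 so coefficients are bit-stable
    return out + 0.0


def estimate_axis(left_eye, right_eye) -> LineCoefficients:
    """Symmetry axis from one frame's eye centroids.

    The interocular direction (normalized) supplies (a, b) — the axis
    normal — and c places the line through the midpoint.
    """
    p = np.asarray(getattr(left_eye, "as_array", lambda: left_eye)(), dtype=float)
    q = np.asarray(getattr(right_eye, "as_array", lambda: right_eye)(), dtype=float)
    d = q - p
    if np.hypot(*d) <= _EPS:
        raise DegenerateGeometryError(f"coincident eye centroids at {p}")
    mid = 0.5 * (p + q)
    abc = np.array([[d[0], d[1], -(d[0] * mid[0] + d[1] * mid[1])]])
    a, b, c = _normalize_abc(abc)[0]
    return LineCoefficients(float(a), float(b), float(c))


def point_line_distance(p, line) -> float:
    """Perpendicular distance |a·x + b·y + c| / sqrt(a² + b²) in pixels.

    Accepts any (a, b, c) scaling; the normalization makes the result
    invariant to rescaling the coefficients by a nonzero constant.
    """
    x, y = (p.x, p.y) if hasattr(p, "x") else (float(p[0]), float(p[1]))
    a, b, c = line
    norm = np.hypot(a, b)
    if norm <= _EPS:
        raise DegenerateGeometryError("degenerate line: a and b both (near) zero")
    return float(abs(a * x + b * y + c) / norm)


def points_line_distances(points: np.ndarray, abc: np.ndarray) -> np.ndarray:
    """Vectorized |a x + b y + c| / ||(a,b)|| for per-frame points and lines.

    ``points``: (n, 2); ``abc``: (n, 3) or (3,) broadcast to all points.
    """
    points = np.asarray(points, dtype=float)
    abc = np.atleast_2d(np.asarray(abc, dtype=float))
    norm = np.hypot(abc[:, 0], abc[:, 1])
    if np.any(norm <= _EPS):
        raise DegenerateGeometryError("degenerate line in series")
    num = np.abs(abc[:, 0] * points[:, 0] + abc[:, 1] * points[:, 1] + abc[:, 2])
    return num / norm


@dataclass
class SymmetryAxisSeries:
    """One symmetry axis per frame with valid eye data."""

    frames: np.ndarray  # (n,) int
    abc: np.ndarray     # (n, 3) unit-normalized

    def __len__(self) -> int:
        return int(self.frames.size)

    def line_at(self, index: int) -> LineCoefficients:
        return LineCoefficients(*self.abc[index])


def axis_series(eyes: EyeTrackPair) -> SymmetryAxisSeries:
    """Per-frame symmetry axes from preprocessed eye tracks.

    Frames where either centroid is missing, or the centroids coincide,
    are omitted (and logged), not interpolated.
    """
    ok = eyes.both_valid.copy()
    d = eyes.right.xy - eyes.left.xy
    ipd = np.hypot(d[:, 0], d[:, 1])
    degenerate = ok & (ipd <= _EPS)
    if np.any(degenerate):
        logger.warning(
            "axis_series: dropping %d frame(s) with coincident eye centroids",
            int(degenerate.sum()),
        )
        ok &= ~degenerate
    if not np.any(ok):
        raise InsufficientDataError("no frames with valid, non-degenerate eye data")
    mid = 0.5 * (eyes.left.xy[ok] + eyes.right.xy[ok])
    dv = d[ok]
    abc = np.column_stack([dv, -(dv * mid).sum(axis=1)])
    return SymmetryAxisSeries(frames=eyes.frames[ok].copy(), abc=_normalize_abc(abc))
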