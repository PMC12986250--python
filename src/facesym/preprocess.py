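"""Track cleaning: single-frame gap interpolation and jump-artifact filtering.

Detection dropouts lasting one frame are filled by linear interpolation
(the coordinate-wise midpoint of the two neighboring frames). Jump
artifacts — non-physiological displacements of an eye centroid between
consecutive frames — are flagged whenever the step exceeds a fraction
(default 10%) of that frame's interocular distance, and the offending
coordinate is replaced by the average of its two neighboring frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import EyeTrackPair, InsufficientDataError, MarkerTrack

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Audit trail of the preprocessing edits applied to a recording."""

    replaced_frames: list[tuple[str, int]] = field(default_factory=list)
    interpolated_frames: list[tuple[str, int]] = field(default_factory=list)


def interpolate_single_gaps(
    track: MarkerTrack, report: FilterReport | None = None
) -> MarkerTrack:
    """Fill isolated single-frame dropouts by the midpoint of their neighbors.

    Only invalid frames whose immediate neighbors on both sides are valid
    are filled; longer gaps stay invalid and are excluded downstream.
    """
    if track.n_valid < 2:
        raise InsufficientDataError(
            f"track {track.marker_id!r}: need >=2 valid frames, have {track.n_valid}"
        )
    out = track.copy()
    v = out.valid
    fill = np.zeros_like(v)
    fill[1:-1] = ~v[1:-1] & v[:-2] & v[2:]
    if np.any(fill):
        idx = np.flatnonzero(fill)
        out.xy[idx] = 0.5 * (out.xy[idx - 1] + out.xy[idx + 1])
        out.valid[idx] = True
        if report is not None:
            report.interpolated_frames.extend(
                (track.marker_id, int(track.frames[i])) for i in idx
            )
    return out


def _filter_track_jumps(
    xy: np.ndarray, thresholds: np.ndarray, marker_id: str, frames: np.ndarray
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Single left-to-right pass over one track.

    Each frame's step is measured against the working (already corrected)
    previous frame, so a replaced artifact restores trajectory continuity
    and the return step back to the clean path is not itself flagged.
    Replacement value: mean of the (corrected) previous and (original)
    next frame. First/last frames cannot be replaced (no two neighbors).
    """
    n = xy.shape[0]
    work = xy.copy()
    replaced: list[tuple[str, int]] = []
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    candidates = list(np.flatnonzero(steps > thresholds[1:]) + 1)
    if not candidates:
        return work, replaced
    i = 0
    recheck = -1
    while i < len(candidates) or recheck >= 0:
        if recheck >= 0 and (i >= len(candidates) or recheck <= candidates[i]):
            t = recheck
            if i < len(candidates) and candidates[i] == recheck:
                i += 1
            recheck = -1
        else:
            t = candidates[i]
            i += 1
        step = float(np.hypot(*(xy[t] - work[t - 1])))
        if step <= thresholds[t]:
            continue
        if t == n - 1:
            logger.warning(
                "jump filter: track %r frame %d flagged but has no following "
                "neighbor; left unmodified", marker_id, int(frames[t]),
            )
            continue
        work[t] = 0.5 * (work[t - 1] + xy[t + 1])
        replaced.append((marker_id, int(frames[t])))
        if t + 1 < n:
            recheck = t + 1
    return work, replaced


def filter_centroid_jumps(
    eyes: EyeTrackPair, threshold_fraction: float = 0.10
) -> tuple[EyeTrackPair, FilterReport]:
    """Replace eye-centroid jump artifacts exceeding ``threshold_fraction`` x IPD.

    The threshold is relative to the current frame's pre-replacement
    interocular distance, making it independent of image resolution and
    facial scale; frames whose own IPD is degenerate fall back to the
    recording-median IPD. Requires fully valid eye tracks (run after
    interpolation). All unflagged frames are returned bit-identical.
    """
    if threshold_fraction <= 0:
        raise ValueError(f"threshold_fraction must be positive, got {threshold_fraction}")
    if not np.all(eyes.both_valid):
        raise InsufficientDataError(
            "filter_centroid_jumps requires fully valid eye tracks; "
            "interpolate or trim gaps first"
        )
    ipd = eyes.ipd()
    median_ipd = float(np.median(ipd[ipd > 0])) if np.any(ipd > 0) else np.nan
    ipd_eff = np.where(ipd > 0, ipd, median_ipd)
    if np.any(~np.isfinite(ipd_eff)):
        raise InsufficientDataError("interocular distance degenerate on all frames")
    thresholds = threshold_fraction * ipd_eff

    report = FilterReport()
    out = eyes.copy()
    for track in (out.left, out.right):
        new_xy, replaced = _filter_track_jumps(
            track.xy, thresholds, track.marker_id, track.frames
        )
        track.xy[:] = new_xy
        report.replaced_frames.extend(replaced)
    return out, report


def preprocess_recording(rec, config) -> tuple["Recording", FilterReport]:
    """Interpolate single-frame gaps and filter eye-centroid jumps.

    Marker tracks get gap interpolation always and jump filtering only
    when ``config.filter_marker_tracks`` is set (the filter targets
    eye-detection artifacts; marker detection has its own upstream QC).
    """
    from .model import Recording  # local import avoids cycle at module load

    report = FilterReport()
    eyes = EyeTrackPair(
        interpolate_single_gaps(rec.eyes.left, report),
        interpolate_single_gaps(rec.eyes.right, report),
    )
    if np.all(eyes.both_valid):
        eyes, jump_report = filter_centroid_jumps(eyes, config.jump_threshold_fraction)
        report.replaced_frames.extend(jump_report.replaced_frames)
    else:
        logger.warning(
            "recording %s: eye tracks retain multi-frame gaps; jump filter "
            "restricted frames will be dropped downstream", rec.recording_id,
        )
    markers = {}
    for mid, track in rec.markers.items():
        try:
            cleaned = interpolate_single_gaps(track, report)
        except InsufficientDataError:
            cleaned = track.copy()
        markers[mid] = cleaned
    if config.filter_marker_tracks:
        ipd = eyes.ipd()
        median_ipd = float(np.median(ipd[ipd > 0]))
        ipd_eff = np.where(ipd > 0, ipd, median_ipd)
        thresholds = config.jump_threshold_fraction * ipd_eff
        for mid, track in markers.items():
            if np.all(track.valid) and len(track) == len(eyes.left):
                new_xy, replaced = _filter_track_jumps(
                    track.xy, thresholds, mid, track.frames
                )
                track.xy[:] = new_xy
                report.replaced_frames.extend(replaced)
    clean = Recording(
        recording_id=rec.recording_id,
        exercise=rec.exercise,
        fps=rec.fps,
        markers=markers,
        eyes=eyes,
        label=rec.label,
    )
    return clean, report
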