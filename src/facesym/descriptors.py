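"""Robust normalization and dispersion descriptors of feature series.

Each feature series of a recording is normalized with a robust z-score
(median/MAD based, applied per feature per recording), then summarized
by three dispersion measures of the normalized series (STD, MAD, IQR)
and three of its first derivative (dSTD, dMAD, dIQR) — the d-prefixed
descriptors capture frame-to-frame movement-velocity variability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import IQR_NORMAL, PipelineConfig
from .features import FEATURE_RATIO, FEATURE_VERTDIST, FeatureSeries
from .model import InsufficientDataError, Recording

logger = logging.getLogger(__name__)

DESCRIPTOR_STATS = ("STD", "MAD", "IQR", "dSTD", "dMAD", "dIQR")
ANALYSIS_FEATURES = (FEATURE_VERTDIST, FEATURE_RATIO)


@dataclass
class DescriptorSet:
    """The six dispersion descriptors of one feature in one recording."""

    recording_id: str
    feature_name: str
    STD: float
    MAD: float
    IQR: float
    dSTD: float
    dMAD: float
    dIQR: float

    def as_dict(self) -> dict:
        return {
            "recording_id": self.recording_id,
            "feature": self.feature_name,
            **{k: getattr(self, k) for k in DESCRIPTOR_STATS},
        }


def robust_zscore(series: FeatureSeries, mad_scale: float = 1.4826) -> FeatureSeries:
    """(x - median) / (mad_scale * MAD), per feature per recording.

    Falls back to a normal-consistent IQR-based scale when the MAD is
    zero; a fully constant series maps to all zeros with a warning.
    """
    if len(series) < 3:
        raise InsufficientDataError(
            f"{series.name}: robust z-score needs >=3 samples, have {len(series)}"
        )
    x = series.values
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = mad_scale * mad
    if scale <= 0:
        iqr = float(np.subtract(*np.percentile(x, [75, 25])))
        scale = iqr / IQR_NORMAL
        if scale > 0:
            logger.warning(
                "%s/%s: MAD is zero; using IQR-based scale for robust z-score",
                series.recording_id, series.name,
            )
    if scale <= 0:
        logger.warning(
            "%s/%s: constant series; robust z-score set to zeros",
            series.recording_id, series.name,
        )
        z = np.zeros_like(x)
    else:
        z = (x - med) / scale
    return FeatureSeries(series.recording_id, series.name, series.frames.copy(), z,
                         series.meta)


def _contiguous_segments(frames: np.ndarray) -> list[slice]:
    breaks = np.flatnonzero(np.diff(frames) != 1)
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks + 1, [frames.size]])
    return [slice(int(a), int(b)) for a, b in zip(starts, stops)]


def first_derivative(
    series: FeatureSeries, fps: float = 1.0, units: str = "per_frame"
) -> FeatureSeries:
    """Forward difference x(t+1) - x(t) within contiguous frame runs.

    Differences are never taken across frame gaps; each contiguous run of
    n frames contributes n-1 samples, indexed by the run's leading frame.
    ``per_second`` units multiply by fps.
    """
    if len(series) < 2:
        raise InsufficientDataError(f"{series.name}: derivative needs >=2 samples")
    out_frames: list[np.ndarray] = []
    out_values: list[np.ndarray] = []
    for seg in _contiguous_segments(series.frames):
        if seg.stop - seg.start < 2:
            continue
        out_frames.append(series.frames[seg][:-1])
        out_values.append(np.diff(series.values[seg]))
    if not out_frames:
        raise InsufficientDataError(
            f"{series.name}: no contiguous run of >=2 frames to differentiate"
        )
    values = np.concatenate(out_values)
    if units == "per_second":
        values = values * fps
    elif units != "per_frame":
        raise ValueError(f"unknown derivative units {units!r}")
    return FeatureSeries(series.recording_id, f"d{series.name}",
                         np.concatenate(out_frames), values, series.meta)


def dispersion(
    values: np.ndarray,
    mad_scale: float = 1.4826,
    quantile_method: str = "linear",
) -> tuple[float, float, float]:
    """(STD, MAD, IQR) of a sample.

    STD is the sample (n-1) standard deviation; MAD is ``mad_scale`` x
    the raw median absolute deviation; IQR is Q3 - Q1 under the given
    quantile interpolation method.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("dispersion needs >=2 samples")
    std = float(np.std(values, ddof=1))
    med = np.median(values)
    mad = mad_scale * float(np.median(np.abs(values - med)))
    q1, q3 = np.percentile(values, [25, 75], method=quantile_method)
    return std, mad, float(q3 - q1)


def descriptor_set(
    series: FeatureSeries, fps: float, config: PipelineConfig | None = None
) -> DescriptorSet:
    """All six descriptors for one feature series of one recording.

    Default pipeline order: robust z-score first, then the first
    derivative of the normalized series (config-switchable).
    """
    config = config or PipelineConfig()
    if config.normalize_before_derivative:
        base = robust_zscore(series, config.mad_scale)
        deriv = first_derivative(base, fps, config.derivative_units)
    else:
        base = robust_zscore(series, config.mad_scale)
        deriv = robust_zscore(
            first_derivative(series, fps, config.derivative_units), config.mad_scale
        )
    std, mad, iqr = dispersion(base.values, config.mad_scale, config.quantile_method)
    dstd, dmad, diqr = dispersion(deriv.values, config.mad_scale, config.quantile_method)
    return DescriptorSet(series.recording_id, series.name,
                         std, mad, iqr, dstd, dmad, diqr)


def build_descriptor_table(
    recordings: list[Recording], config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Descriptor rows (recording x feature) for a cohort.

    Runs preprocessing, axis estimation and feature extraction per
    recording; recordings failing any stage are excluded with a logged
    reason and returned in the exclusion list, never silently dropped.

    Returns (table, exclusions) where the table has one row per
    recording x feature with columns recording_id, feature, the six
    descriptors, and label.
    """
    from .geometry import axis_series
    from .features import compute_features
    from .preprocess import preprocess_recording
    from .model import FaceSymError

    config = config or PipelineConfig()
    rows: list[dict] = []
    exclusions: list[tuple[str, str]] = []
    for rec in recordings:
        try:
            clean, _ = preprocess_recording(rec, config)
            axes = axis_series(clean.eyes)
            feats = compute_features(clean, axes, config)
            for name in ANALYSIS_FEATURES:
                ds = descriptor_set(feats[name], clean.fps, config)
                row = ds.as_dict()
                row["label"] = rec.label.value if rec.label is not None else None
                rows.append(row)
        except FaceSymError as exc:
            logger.warning("excluding recording %s: %s", rec.recording_id, exc)
            exclusions.append((rec.recording_id, str(exc)))
    table = pd.DataFrame(
        rows,
        columns=["recording_id", "feature", *DESCRIPTOR_STATS, "label"],
    )
    return table, exclusions


def descriptor_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a descriptor table to one row per recording.

    Columns are ``<feature>_<stat>`` (e.g. ``VertDist_dSTD``) plus
    ``label``; this is the wide layout consumed by the statistics stage.
    """
    wide = table.pivot(index="recording_id", columns="feature",
                       values=list(DESCRIPTOR_STATS))
    wide.columns = [f"{feat}_{stat}" for stat, feat in wide.columns]
    wide = wide[sorted(wide.columns, key=lambda c: (c.split("_")[0], DESCRIPTOR_STATS.index(c.split("_")[1])))]
    labels = table.drop_duplicates("recording_id").set_index("recording_id")["label"]
    wide["label"] = labels
    return wide
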