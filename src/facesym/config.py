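"""Pipeline configuration.

All numerically consequential choices live here so a run can be
reproduced from its config snapshot alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import Exercise, ValidationError

#: Scale factor making the MAD a consistent estimator of the SD under normality.
MAD_NORMAL_CONSISTENCY = 1.4826

#: IQR of the standard normal; used for the IQR-based fallback scale.
IQR_NORMAL = 1.3489795003921634


@dataclass
class PipelineConfig:
    """Tunable parameters of the asymmetry pipeline.

    jump_threshold_fraction
        Eye-centroid displacement threshold as a fraction of the per-frame
        interocular distance (default 0.10, i.e. 10% of IPD).
    mad_scale
        Multiplier applied to the raw MAD in robust z-scores and in the
        MAD dispersion descriptor; 1.4826 makes it SD-consistent under
        normality. Set to 1.0 for raw-MAD mode.
    derivative_units
        "per_frame" (forward difference) or "per_second" (difference x fps).
    ratio_orientation
        "left_over_right" (image-left marker distance in the numerator)
        or "right_over_left".
    quantile_method
        Quantile interpolation used for the IQR (numpy method name).
    roc_positive_class
        Which label counts as positive in ROC analysis ("S" or "AS").
    normalize_before_derivative
        If True (default) the robust z-score is applied before the first
        derivative is taken; if False, after.
    filter_marker_tracks
        Apply the IPD-relative jump filter to non-eye marker tracks too
        (default off: it targets eye-centroid detection artifacts).
    holm_correction
        Apply Holm step-down adjustment across descriptors (default off).
    marker_pair_overrides
        Optional {exercise: (left_id, right_id)} replacing the default
        analysis pair.
    """

    jump_threshold_fraction: float = 0.10
    mad_scale: float = MAD_NORMAL_CONSISTENCY
    derivative_units: str = "per_frame"
    ratio_orientation: str = "left_over_right"
    quantile_method: str = "linear"
    roc_positive_class: str = "S"
    rng_seed: int = 0
    normalize_before_derivative: bool = True
    filter_marker_tracks: bool = False
    holm_correction: bool = False
    ratio_degeneracy_floor: float = 1e-6
    alpha: float = 0.05
    marker_pair_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.jump_threshold_fraction < 1.0:
            raise ValidationError(
                "jump_threshold_fraction must lie in (0, 1), got "
                f"{self.jump_threshold_fraction}"
            )
        if self.mad_scale <= 0:
            raise ValidationError(f"mad_scale must be positive, got {self.mad_scale}")
        if self.derivative_units not in ("per_frame", "per_second"):
            raise ValidationError(f"unknown derivative_units {self.derivative_units!r}")
        if self.ratio_orientation not in ("left_over_right", "right_over_left"):
            raise ValidationError(f"unknown ratio_orientation {self.ratio_orientation!r}")
        if self.roc_positive_class not in ("S", "AS"):
            raise ValidationError(f"roc_positive_class must be 'S' or 'AS'")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        self.marker_pair_overrides = {
            Exercise(k): tuple(v) for k, v in self.marker_pair_overrides.items()
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["marker_pair_overrides"] = {
            k.value: list(v) for k, v in self.marker_pair_overrides.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
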