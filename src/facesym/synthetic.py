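"""Seeded simulator of facial-exercise marker and eye-centroid trajectories.

Emulates 50 fps trajectory streams of a face performing periodic
exercise repetitions in front of a static camera: eye centroids and the
exercise's homologous marker pair are placed mirror-symmetrically about
a vertical midline at rest; each repetition displaces the pair along the
exercise axis with a smooth raised-cosine pulse. Asymmetric execution is
modeled by the two mechanisms that make real executions look asymmetric:
a reduced amplitude on one side (right amplitude = rho x left) and/or a
phase lag of one side. Rigid head drift and roll, Gaussian detection
jitter, single-frame detection dropouts and isolated eye-centroid jump
artifacts can all be layered on top, each from its own RNG stream so
toggling artifacts does not change the motion realization.

Ground truth: an execution is symmetric (S) iff rho == 1 and the phase
lag is 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .model import (
    EYE_LEFT_ID,
    EYE_RIGHT_ID,
    EyeTrackPair,
    Exercise,
    MarkerTrack,
    RaterPanel,
    Recording,
    SymmetryLabel,
    ValidationError,
)

#: ids of the 13 non-analysis markers, placed statically on the face.
STATIC_MARKER_IDS = tuple(f"{i:02d}" for i in range(20, 33))

_ACTIVE_FRACTION = 0.6  # fraction of each repetition period spent moving


@dataclass
class SimulationParams:
    """Acquisition and motion parameters for one simulated recording.

    Defaults mirror the acquisition protocol being emulated: 50 fps
    video, 20 s per exercise, interocular distance ~120 px with the
    analysis markers +/-40 px lateral of the midline, and ~8 exercise
    repetitions over the recording.
    """

    exercise: Exercise = Exercise.EYEBROW_RAISING
    fps: float = 50.0
    duration_s: float = 20.0
    n_repetitions: int = 8
    amplitude_px: float = 40.0
    asymmetry_amplitude: float = 1.0     # rho: right-side / left-side amplitude
    asymmetry_phase_frames: int = 0      # lag of the right side, in frames
    noise_sd_px: float = 1.0
    tremor_sd_px: float = 1.0            # smooth per-marker physiological micro-motion
    tremor_timescale_s: float = 0.5
    head_drift_px_per_s: float = 2.0     # peak translational velocity of the head wobble
    head_roll_deg_per_s: float = 0.5     # peak angular velocity of the head wobble
    artifact_rate: float = 0.0           # per-frame eye-centroid jump probability
    artifact_magnitude_ipd: float = 0.15
    dropout_rate: float = 0.0            # per-frame single-frame dropout probability
    seed: int = 0
    ipd_px: float = 120.0
    marker_offset_px: float = 40.0
    face_center: tuple[float, float] = (960.0, 540.0)
    waveform: str = "raised_cosine"      # or "sinusoid"

    def __post_init__(self) -> None:
        self.exercise = Exercise(self.exercise)
        if not 0.0 < self.asymmetry_amplitude <= 1.0:
            raise ValidationError(
                f"asymmetry_amplitude must lie in (0, 1], got {self.asymmetry_amplitude}"
            )
        if min(self.fps, self.duration_s, self.amplitude_px) <= 0:
            raise ValidationError("fps, duration_s and amplitude_px must be positive")
        for name in ("artifact_rate", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.asymmetry_phase_frames < 0:
            raise ValidationError("asymmetry_phase_frames must be >= 0")
        if self.waveform not in ("raised_cosine", "sinusoid"):
            raise ValidationError(f"unknown waveform {self.waveform!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    def truth(self) -> SymmetryLabel:
        symmetric = self.asymmetry_amplitude == 1.0 and self.asymmetry_phase_frames == 0
        return SymmetryLabel.S if symmetric else SymmetryLabel.AS


@dataclass
class SimulationTruth:
    """What was injected, for validating the pipeline against ground truth."""

    label: SymmetryLabel
    artifact_frames: dict[str, list[int]] = field(default_factory=dict)
    dropout_frames: dict[str, list[int]] = field(default_factory=dict)


def _pulse_signal(t: np.ndarray, n_frames: int, n_repetitions: int,
                  waveform: str, rep_scales: np.ndarray | None = None) -> np.ndarray:
    """Exercise activation s(t) >= 0.

    Raised-cosine pulses occupy the first 60% of each repetition period,
    leaving rest intervals between repetitions as in real exercise
    execution; negative times (phase lag spill-over) map to rest.
    ``rep_scales`` scales each repetition individually (no execution
    repeats a movement with identical amplitude); the same scales are
    applied to both facial sides so symmetry is unaffected.
    """
    period = n_frames / n_repetitions
    if waveform == "sinusoid":
        s = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / period))
    else:
        u = np.mod(t, period) / period
        s = np.where(u < _ACTIVE_FRACTION,
                     0.5 * (1.0 - np.cos(2.0 * np.pi * u / _ACTIVE_FRACTION)),
                     0.0)
    if rep_scales is not None:
        rep = np.clip(np.floor_divide(t, period).astype(int), 0,
                      rep_scales.size - 1)
        s = s * rep_scales[rep]
    return np.where(t < 0, 0.0, s)


def _rest_layout(params: SimulationParams) -> dict[str, np.ndarray]:
    """Rest positions of eyes and all 17 markers, mirror-symmetric about x=cx."""
    cx, cy = params.face_center
    half_ipd = params.ipd_px / 2.0
    off = params.marker_offset_px
    layout = {
        EYE_LEFT_ID: np.array([cx - half_ipd, cy]),
        EYE_RIGHT_ID: np.array([cx + half_ipd, cy]),
        # eyebrow pair sits above the eyes (image y decreases upward)
        "00": np.array([cx - off, cy - 60.0]),
        "01": np.array([cx + off, cy - 60.0]),
        # mouth-corner pair sits below
        "10": np.array([cx - off, cy + 80.0]),
        "11": np.array([cx + off, cy + 80.0]),
    }
    # remaining markers ring the face; one (the last) acts as a static reference
    angles = np.linspace(0.0, 2.0 * np.pi, len(STATIC_MARKER_IDS), endpoint=False)
    for mid, ang in zip(STATIC_MARKER_IDS, angles):
        layout[mid] = np.array([cx + 140.0 * np.cos(ang), cy + 170.0 * np.sin(ang)])
    return layout


def _exercise_directions(exercise: Exercise) -> tuple[np.ndarray, np.ndarray]:
    """Unit displacement directions (left marker, right marker).

    Eyebrow raising moves straight up; smiling pulls the mouth corners
    obliquely outward and upward, mirrored across the midline.
    """
    if exercise == Exercise.EYEBROW_RAISING:
        return np.array([0.0, -1.0]), np.array([0.0, -1.0])
    return np.array([-0.6, -0.8]), np.array([0.6, -0.8])


def _isolated_frames(rng: np.random.Generator, n_frames: int, rate: float) -> np.ndarray:
    """Interior frames hit by a per-frame Bernoulli(rate), thinned so no two
    selected frames are adjacent (keeps injected events single-frame)."""
    if rate <= 0.0:
        return np.empty(0, dtype=int)
    hits = np.flatnonzero(rng.random(n_frames) < rate)
    hits = hits[(hits >= 2) & (hits <= n_frames - 3)]
    keep: list[int] = []
    for h in hits:
        if not keep or h - keep[-1] >= 3:
            keep.append(int(h))
    return np.asarray(keep, dtype=int)


def simulate_recording(
    params: SimulationParams,
    *,
    recording_id: str | None = None,
    with_truth: bool = False,
):
    """Generate one recording; deterministic given ``params.seed``.

    Returns ``(Recording, label)`` or, with ``with_truth=True``,
    ``(Recording, label, SimulationTruth)`` carrying the injected
    artifact/dropout frames.
    """
    n = params.n_frames
    t = np.arange(n, dtype=float)
    seq = np.random.SeedSequence(params.seed)
    motion_rng, artifact_rng, dropout_rng = (
        np.random.default_rng(s) for s in seq.spawn(3)
    )

    layout = _rest_layout(params)
    ids = list(layout.keys())
    pos = np.stack([np.broadcast_to(layout[i], (n, 2)).copy() for i in ids])

    # exercise displacement of the active pair
    left_id, right_id = {
        Exercise.EYEBROW_RAISING: ("00", "01"),
        Exercise.SMILING: ("10", "11"),
    }[params.exercise]
    dir_l, dir_r = _exercise_directions(params.exercise)
    rep_scales = motion_rng.uniform(0.7, 1.3, size=params.n_repetitions + 1)
    s_left = _pulse_signal(t, n, params.n_repetitions, params.waveform, rep_scales)
    s_right = _pulse_signal(t - params.asymmetry_phase_frames, n,
                            params.n_repetitions, params.waveform, rep_scales)
    amp = params.amplitude_px
    rho = params.asymmetry_amplitude
    pos[ids.index(left_id)] += amp * s_left[:, None] * dir_l
    pos[ids.index(right_id)] += rho * amp * s_right[:, None] * dir_r

    # rigid head motion: a participant holding a "neutral" position wobbles
    # slowly rather than drifting away, so roll and drift are slow
    # sinusoids whose PEAK velocities are the configured rates
    omega = 2.0 * np.pi * 0.1  # rad/s; ~0.1 Hz postural sway
    time_s = t / params.fps
    roll_phase = motion_rng.uniform(0.0, 2.0 * np.pi)
    drift_angle = motion_rng.uniform(0.0, 2.0 * np.pi)
    drift_phase = motion_rng.uniform(0.0, 2.0 * np.pi)
    theta = (np.deg2rad(params.head_roll_deg_per_s) / omega) * np.sin(
        omega * time_s + roll_phase
    )
    drift = (params.head_drift_px_per_s / omega) * np.outer(
        np.sin(omega * time_s + drift_phase),
        [np.cos(drift_angle), np.sin(drift_angle)],
    )
    if params.head_roll_deg_per_s != 0.0:
        c, s = np.cos(theta), np.sin(theta)
        center = np.asarray(params.face_center)
        rel = pos - center
        pos = np.stack(
            [c * rel[..., 0] - s * rel[..., 1], s * rel[..., 0] + c * rel[..., 1]],
            axis=-1,
        ) + center
    pos += drift

    # smooth, temporally correlated per-marker micro-motion (skin and
    # muscle-tone fluctuation plus slow detection drift): low-pass
    # filtered Gaussian noise, independent per track and axis
    if params.tremor_sd_px > 0.0:
        from scipy.ndimage import gaussian_filter1d

        sigma_frames = max(params.tremor_timescale_s * params.fps, 1.0)
        tremor = motion_rng.normal(0.0, 1.0, size=pos.shape)
        tremor = gaussian_filter1d(tremor, sigma_frames, axis=1, mode="reflect")
        sd = tremor.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        pos += params.tremor_sd_px * tremor / sd

    if params.noise_sd_px > 0.0:
        pos += motion_rng.normal(0.0, params.noise_sd_px, size=pos.shape)

    truth = SimulationTruth(label=params.truth())

    # isolated eye-centroid jump artifacts, magnitude relative to true IPD
    ipd_t = np.linalg.norm(
        pos[ids.index(EYE_RIGHT_ID)] - pos[ids.index(EYE_LEFT_ID)], axis=1
    )
    for eye_id in (EYE_LEFT_ID, EYE_RIGHT_ID):
        frames = _isolated_frames(artifact_rng, n, params.artifact_rate)
        if frames.size:
            ang = artifact_rng.uniform(0.0, 2.0 * np.pi, size=frames.size)
            mag = params.artifact_magnitude_ipd * ipd_t[frames]
            pos[ids.index(eye_id), frames] += mag[:, None] * np.column_stack(
                [np.cos(ang), np.sin(ang)]
            )
        truth.artifact_frames[eye_id] = frames.tolist()

    # isolated single-frame detection dropouts on eyes and the active pair
    valid = {i: np.ones(n, dtype=bool) for i in ids}
    for track_id in (EYE_LEFT_ID, EYE_RIGHT_ID, left_id, right_id):
        frames = _isolated_frames(dropout_rng, n, params.dropout_rate)
        valid[track_id][frames] = False
        truth.dropout_frames[track_id] = frames.tolist()

    frame_idx = np.arange(n)

    def _track(mid: str) -> MarkerTrack:
        xy = pos[ids.index(mid)].copy()
        v = valid[mid]
        xy[~v] = np.nan
        return MarkerTrack(mid, frame_idx.copy(), xy, v.copy())

    label = params.truth()
    rec = Recording(
        recording_id=recording_id
        or f"sim-{params.exercise.value}-{params.seed}",
        exercise=params.exercise,
        fps=params.fps,
        markers={m: _track(m) for m in ids if m not in (EYE_LEFT_ID, EYE_RIGHT_ID)},
        eyes=EyeTrackPair(_track(EYE_LEFT_ID), _track(EYE_RIGHT_ID)),
        label=label,
    )
    if with_truth:
        return rec, label, truth
    return rec, label


def _jitter_subject(
    params: SimulationParams, rng: np.random.Generator, seed: int
) -> SimulationParams:
    """Mild between-subject variation of amplitude and baseline geometry.

    The group-defining asymmetry parameters (rho, phase lag) are kept
    verbatim so planted effects and null configurations stay exact.
    """
    return dataclasses.replace(
        params,
        seed=seed,
        amplitude_px=params.amplitude_px * float(rng.uniform(0.8, 1.2)),
        ipd_px=params.ipd_px * float(rng.uniform(0.92, 1.08)),
        marker_offset_px=params.marker_offset_px * float(rng.uniform(0.9, 1.1)),
        noise_sd_px=params.noise_sd_px * float(rng.uniform(0.8, 1.2)),
        tremor_sd_px=params.tremor_sd_px * float(rng.uniform(0.8, 1.2)),
        n_repetitions=int(np.clip(params.n_repetitions + rng.integers(-2, 3), 3, 20)),
        head_drift_px_per_s=params.head_drift_px_per_s * float(rng.uniform(0.5, 1.5)),
        head_roll_deg_per_s=params.head_roll_deg_per_s * float(rng.uniform(0.5, 1.5)),
    )


def simulate_cohort(
    n_s: int,
    n_as: int,
    s_params: SimulationParams | None = None,
    as_params: SimulationParams | None = None,
    seed: int = 0,
) -> tuple[list[Recording], list[SymmetryLabel]]:
    """Simulate a labeled cohort of symmetric and asymmetric executions.

    Default group parameters: symmetric executions with rho = 1 and no
    lag; asymmetric with right amplitude halved (rho = 0.5) and a 2-frame
    phase lag. Per-recording seeds and between-subject jitter derive
    deterministically from the cohort seed.
    """
    if n_s < 2 or n_as < 2:
        raise ValidationError("cohort needs at least 2 recordings per group")
    s_params = s_params or SimulationParams()
    as_params = as_params or dataclasses.replace(
        s_params, asymmetry_amplitude=0.5, asymmetry_phase_frames=2
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    recordings: list[Recording] = []
    labels: list[SymmetryLabel] = []
    specs = [s_params] * n_s + [as_params] * n_as
    for k, base in enumerate(specs):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        p = _jitter_subject(base, rng, sub_seed)
        rec, label = simulate_recording(
            p, recording_id=f"sim-{base.exercise.value}-{k:03d}-{label_tag(base)}"
        )
        recordings.append(rec)
        labels.append(label)
    return recordings, labels


def label_tag(params: SimulationParams) -> str:
    return params.truth().value


def simulate_rater_panel(
    true_labels: list[SymmetryLabel],
    recording_ids: list[str] | None = None,
    n_raters: int = 3,
    error_rate: float = 0.15,
    seed: int = 0,
) -> RaterPanel:
    """Simulate independent expert raters who flip the true label with
    probability ``error_rate`` (imperfect, chance-corrected agreement)."""
    rng = np.random.default_rng(seed)
    labels = np.array([SymmetryLabel(l).value for l in true_labels], dtype=object)
    flip = rng.random((labels.size, n_raters)) < error_rate
    other = np.where(labels == "S", "AS", "S")
    ratings = np.where(flip, other[:, None], labels[:, None]).astype(object)
    ids = recording_ids or [f"rec-{i:03d}" for i in range(labels.size)]
    return RaterPanel(recording_ids=list(ids), ratings=ratings)
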