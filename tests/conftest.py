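import logging

import numpy as np
import pytest

from facesym import (
    EyeTrackPair,
    MarkerTrack,
    Recording,
    SimulationParams,
    simulate_recording,
)

# degenerate-data warnings are expected throughout; keep test output readable
logging.getLogger("facesym").setLevel(logging.ERROR)
for name in ("facesym.stats", "facesym.descriptors", "facesym.preprocess",
             "facesym.features", "facesym.geometry"):
    logging.getLogger(name).setLevel(logging.ERROR)


def make_track(marker_id, xy, valid=None, start_frame=0):
    xy = np.asarray(xy, dtype=float)
    n = xy.shape[0]
    if valid is None:
        valid = np.ones(n, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
        xy = xy.copy()
        xy[~valid] = np.nan
    return MarkerTrack(marker_id, np.arange(start_frame, start_frame + n), xy, valid)


def make_eyes(left_xy, right_xy, left_valid=None, right_valid=None):
    return EyeTrackPair(
        make_track("eyeL", left_xy, left_valid),
        make_track("eyeR", right_xy, right_valid),
    )


def static_recording(n_frames=10, exercise="eyebrow_raising", label="S",
                     recording_id="rec-static"):
    """A motionless, noise-free recording with mirror-symmetric layout."""
    def const(mid, x, y):
        return make_track(mid, np.tile([x, y], (n_frames, 1)))

    markers = {
        "00": const("00", 460.0, 240.0),
        "01": const("01", 540.0, 240.0),
        "10": const("10", 460.0, 380.0),
        "11": const("11", 540.0, 380.0),
    }
    eyes = make_eyes(np.tile([440.0, 300.0], (n_frames, 1)),
                     np.tile([560.0, 300.0], (n_frames, 1)))
    return Recording(recording_id, exercise, 50.0, markers, eyes, label)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_sim_params():
    """Deterministic, artifact-free symmetric recording parameters."""
    return SimulationParams(
        exercise="smiling",
        noise_sd_px=0.0,
        tremor_sd_px=0.0,
        head_drift_px_per_s=0.0,
        head_roll_deg_per_s=0.0,
        seed=7,
    )


@pytest.fixture
def symmetric_recording(clean_sim_params):
    rec, label = simulate_recording(clean_sim_params)
    return rec
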