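import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tentacular.landmark_io import FrameLandmarks, Trial, TrialMeta

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20211730)


def make_static_trial(tentacles, trial_id="t1", stimulus=(932.0, 512.0),
                      treatment="ventral_24", stimulus_angle=0.0,
                      animal_id="a1", viewing_side="above"):
    """Build a one-frame static trial from explicit (base, tip) pairs.

    Centre at (512, 512), ventral axis along +x (axis_ref to the right),
    so with viewing_side='above' body angles equal standard math angles
    measured after flipping the image y-axis.
    """
    meta = TrialMeta(
        trial_id=trial_id, animal_id=animal_id, experiment="static_position",
        treatment_label=treatment,
        stimulus_present=stimulus_angle is not None,
        stimulus_angle_body=stimulus_angle,
        stimulus_width=24.0, frame_rate_raw=1.0, viewing_side=viewing_side,
    )
    frame = FrameLandmarks(
        frame_index=0, centre=(512.0, 512.0), axis_ref=(692.0, 512.0),
        stimulus=stimulus if stimulus_angle is not None else None,
        tentacles={f"t{i:02d}": bt for i, bt in enumerate(tentacles)},
    )
    return Trial(meta=meta, frames=[frame])


def radial_tentacle(angle_deg, length=80.0, root_radius=180.0,
                    centre=(512.0, 512.0)):
    """(base, tip) for a straight radial tentacle at a body angle.

    Valid for the make_static_trial frame (ventral axis = +x, viewed from
    above): the image y-axis is flipped relative to math convention.
    """
    rad = np.deg2rad(angle_deg)
    cx, cy = centre
    base = (cx + root_radius * np.cos(rad), cy - root_radius * np.sin(rad))
    tip = (base[0] + length * np.cos(rad), base[1] - length * np.sin(rad))
    return base, tip
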