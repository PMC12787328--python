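import numpy as np
import pytest

from frailsense.models import FrailtyProfile, Participant, Trajectory
from frailsense.synthetic import SimulationConfig


@pytest.fixture
def participant():
    return Participant(id="P001", sex="male", age=72.0, height_cm=176.0, weight_kg=80.0)


@pytest.fixture
def zero_noise_config():
    return SimulationConfig(
        n_participants=21, seed=11, position_noise_sd_m=0.0, clinical_noise_sd=0.0
    )


def straight_walk(
    speed=1.2, duration=5.0, rate=10.0, pid="P001", t0=0.0, y0=0.0, z0=1.0
) -> Trajectory:
    """Noiseless constant-speed walk along +x."""
    n = int(np.floor(duration * rate)) + 1
    t = t0 + np.arange(n) / rate
    x = speed * (t - t0)
    return Trajectory(
        participant_id=pid, t=t, x=x, y=np.full(n, y0), z=np.full(n, z0)
    )


@pytest.fixture
def robust_profile():
    return FrailtyProfile()


@pytest.fixture
def frail_profile():
    return FrailtyProfile(weight_loss=1, exhaustion=1, low_activity=1, weakness=1, slowness=1)
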