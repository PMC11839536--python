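import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from glymphkin.synthetic_data import SimulationConfig, VelocityField


@pytest.fixture
def quiet_config():
    """Small noise-free config with no pre-roll: frame 0 is the deposited bolus."""
    return SimulationConfig(
        grid_shape=(48, 48),
        pixel_size=0.1,
        frame_interval=1.0,
        n_frames=11,
        injection_center=(2.4, 2.4),
        origin=(0.0, 0.0),
        bolus_amount=1000.0,
        bolus_sigma=0.4,
        diffusivity=0.0,
        velocity_field=VelocityField(),
        decay_rate=0.0,
        background_level=5.0,
        camera_gain=1.0,
        noise_sigma=0.0,
        seed=7,
        pre_roll=0.0,
        t0_offset=0.0,
    )


@pytest.fixture
def tiny_overrides():
    """Preset overrides that shrink the simulation for fast pipeline tests."""
    return {"n_frames": 16, "pre_roll": 5.0}


def make_uniform_stack(value=7.0, n_frames=3, shape=(8, 8), **kwargs):
    from glymphkin.io_formats import ImageStack

    frames = np.full((n_frames,) + shape, float(value))
    defaults = dict(pixel_size=0.1, frame_interval=1.0)
    defaults.update(kwargs)
    return ImageStack(frames=frames, **defaults)
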