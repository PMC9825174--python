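import numpy as np
import pytest

from smtrack.simkit import SimulationConfig
from smtrack.tracking import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def free_diffusion_config(**overrides) -> SimulationConfig:
    """Config for pure-diffusion trajectories: no removal, no blinking."""
    base = dict(
        n_frames=300,
        diffusion_coefficient=2.11e-2,
        alpha=1.0,
        localization_sigma=0.02,
        bind_lifetime=float("inf"),
        bleach_lifetime=float("inf"),
        blink_on_lifetime=float("inf"),
        motile_fraction=1.0,
        dna_length=1e5,  # effectively unbounded substrate
    )
    base.update(overrides)
    return SimulationConfig(**base)


def make_track(
    positions,
    particle_id=0,
    frames=None,
    frame_interval=0.1,
    channel="test",
    censored_end=False,
):
    positions = np.asarray(positions, dtype=float)
    if frames is None:
        frames = np.arange(positions.size)
    return Trajectory(
        particle_id=particle_id,
        channel=channel,
        frames=np.asarray(frames),
        positions_um=positions,
        frame_interval=frame_interval,
        censored_end=censored_end,
    )
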