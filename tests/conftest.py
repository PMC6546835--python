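import numpy as np
import pytest

from cytoprof.synth import SceneParams, TimeLapseParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_scene_params():
    """A quick-to-render scene used by several module tests."""
    return SceneParams(
        field_size=(400.0, 400.0),
        pixel_size=2.0,
        n_target_cells=30,
        dead_fraction=0.2,
        n_effector_cells=40,
        infiltration_decay_length=150.0,
        seed=7,
    )


@pytest.fixture
def small_timelapse_params():
    """A small movie with a handful of kill events."""
    return TimeLapseParams(
        field_size=(300.0, 300.0),
        pixel_size=2.0,
        n_target_cells=15,
        dead_fraction=0.0,
        n_effector_cells=20,
        infiltration_decay_length=250.0,
        n_frames=25,
        frame_interval=5.0,
        effector_step_sd=5.0,
        contact_distance=4.0,
        kill_probability_per_contact=1.0,
        pi_delay_mean=20.0,
        pi_delay_sd=4.0,
        seed=11,
    )
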