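import numpy as np
import pytest

import larvaswim as lw


@pytest.fixture(scope="session")
def survey_scene():
    """The standard pipeline-validation scene: 20 constant-velocity larvae,
    60 frames at 6 fps, mild sensor noise. Rendered once per session."""
    spec = lw.make_speed_survey_scene(
        n_larvae=20, n_frames=60, fps=6.0, speed_range_cm_s=(0.5, 5.0),
        noise_sigma=0.02, seed=101,
    )
    seq, truth = lw.render_sequence(spec)
    return spec, seq, truth


@pytest.fixture(scope="session")
def small_scene():
    """One slow larva on a small noiseless frame, for cheap exact checks."""
    spec = lw.SceneSpec(
        width_px=200, height_px=160, n_frames=8, fps=5.0, cm_per_px=0.05,
        noise_sigma=0.0,
        larvae=(
            lw.LarvaSpec(
                start_px=(40.0, 80.0),
                trajectory_kind="constant_velocity",
                trajectory_params={"velocity_cm_s": (1.0, 0.0)},
            ),
        ),
        seed=7,
    )
    seq, truth = lw.render_sequence(spec)
    return spec, seq, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
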