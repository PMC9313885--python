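import numpy as np
import pytest

from neophobia import (
    ArenaConfig,
    RenderParams,
    SimParams,
    Trajectory,
    object_arena,
    odor_arena,
    render_video,
)


@pytest.fixture
def arena() -> ArenaConfig:
    return object_arena()


@pytest.fixture
def odor() -> ArenaConfig:
    return odor_arena()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_trajectory(x, y, fps=25.0, subject_id="t0", arena=None, **kw) -> Trajectory:
    return Trajectory(
        subject_id=subject_id,
        x=np.asarray(x, float),
        y=np.asarray(y, float),
        fps=fps,
        arena=arena,
        **kw,
    )


@pytest.fixture
def short_sim(arena) -> Trajectory:
    """A 20-s simulated trial in the object arena (deterministic)."""
    from neophobia import simulate_trajectory

    params = SimParams(duration_s=20.0, seed=7)
    return simulate_trajectory(params, arena)


@pytest.fixture
def clean_video(short_sim, arena):
    """Noise-free rendered stack of the short trial, with ground truth."""
    rp = RenderParams(noise_sd=0.0, draw_stimulus=False)
    return render_video(short_sim, rp, arena), short_sim, rp
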