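import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import ndimage

from migflow import RunConfig, SimulationConfig, simulate_stack
from migflow.pipeline import analyze_stack

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def textured_frame(shape=(96, 128), sigma=2.0, amplitude=100.0, seed=7):
    """Smooth random texture (periodic) with mean 500, used as flow target."""
    rng = np.random.default_rng(seed)
    tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), sigma, mode="wrap")
    return 500.0 + amplitude * tex / tex.std()


def shifted(frame, dx, dy):
    """Periodic subpixel shift of a frame by (dx, dy) pixels."""
    return ndimage.shift(frame, (dy, dx), order=3, mode="grid-wrap")


@pytest.fixture(scope="session")
def textured():
    return textured_frame()


@pytest.fixture(scope="session")
def disciplined_run():
    """One full q=1 simulation analysed end-to-end (shared across tests)."""
    cfg = SimulationConfig(q=1.0, seed=7)
    stack, tracks = simulate_stack(cfg)
    rc = RunConfig(out_dir="scratch_unused")
    summary, inter = analyze_stack(stack, rc)
    return cfg, stack, tracks, summary, inter


def small_sim_config(**kw):
    """Compact simulation for fast tests; geometry keeps all cells in-field."""
    defaults = dict(
        n_cells=20,
        n_frames=6,
        field_size=(192, 96),
        origin_x=96.0,
        start_x_sd=12.0,
        seed=5,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)
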