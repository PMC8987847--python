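import numpy as np
import pytest

from turntable3d.bundle import adjust_with_rejection, initialize_turntable
from turntable3d.synthetic import midsize_scene, simulate_capture


@pytest.fixture(scope="session")
def small_noiseless():
    """Tiny noiseless mid-size capture: 2 cameras, 12 steps of 30°."""
    scene = midsize_scene(
        n_cameras=2, n_steps=12, step_deg=30.0, dot_count=40,
        sigma_px=0.0, outlier_fraction=0.0, with_plant=False, seed=11,
    )
    tracks, truth = simulate_capture(scene)
    return scene, tracks, truth


@pytest.fixture(scope="session")
def small_noisy_solution():
    """One solved noisy bundle shared across tests (σ=0.3 px, 2% outliers)."""
    scene = midsize_scene(
        n_cameras=2, n_steps=18, step_deg=20.0, dot_count=80,
        sigma_px=0.3, outlier_fraction=0.02, with_plant=False, seed=5,
    )
    tracks, truth = simulate_capture(scene)
    problem = initialize_turntable(scene.rig, tracks, scene.n_steps, scene.step_deg)
    solution = adjust_with_rejection(problem)
    return scene, tracks, truth, solution


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
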