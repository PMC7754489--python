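import numpy as np
import pytest

from perfcensor import PhantomSpec, RunConfig, run_pipeline, synthesize


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A 128-square phantom with the same scene structure as the default:
    two vessels casting ghost bands through a central-WM disk, scaled down
    for fast unit tests."""
    params = dict(
        image_shape=(128, 128),
        brain_radius=60,
        wm_radius=52,
        central_margin=30,
        ghost_spacing=20,
        vessel_cluster_sizes=(24, 10),  # ~ the top-0.3% voxel budget at 128**2
        vessel_ro_offsets=(16, 21),
        n_perforators=6,
        n_on_ghost=0,
        seed=0,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def small_config(**overrides) -> RunConfig:
    """Pipeline config matched to the small phantom geometry."""
    params = dict(wm_margin=30, phase_bg_window=21, detrend_window=40)
    params.update(overrides)
    return RunConfig(**params)


@pytest.fixture(scope="session")
def default_phantom():
    """One full-size phantom (256-square, 2 vessels, 4 of 12 perforators on
    ghost bands) shared by the heavier integration tests."""
    spec = PhantomSpec(seed=1, n_on_ghost=4)
    series, truth = synthesize(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def default_pipeline(default_phantom):
    spec, series, truth = default_phantom
    result = run_pipeline(series, truth.wm_mask, truth.brain_mask)
    return spec, series, truth, result


@pytest.fixture(scope="session")
def small_noisy_phantom():
    spec = small_phantom_spec(seed=3, n_on_ghost=2)
    series, truth = synthesize(spec)
    return spec, series, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
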