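import numpy as np
import pytest

from flimflux.synthetic import (
    AcquisitionConfig,
    CellSpec,
    SceneConfig,
    SensorModel,
    build_scene,
    render_decay_cube,
)
from flimflux.tcspc import FitOptions, filter_fits, fit_cube


@pytest.fixture(scope="session")
def sensor():
    return SensorModel()


@pytest.fixture(scope="session")
def disk_scene(sensor):
    """One large soma disk filling most of a 32x32 frame (609 cell pixels)."""
    cfg = SceneConfig(
        width=32,
        height=32,
        cells=[
            CellSpec(
                soma_center=(16, 16), soma_radius=14, nucleus_radius=0,
                soma_atp=4.0, atp_noise_sd=0.2,
            )
        ],
        seed=1,
    )
    return build_scene(cfg, sensor)


@pytest.fixture(scope="session")
def fitted_budgets(disk_scene):
    """Rendered + fitted + filtered cubes at photon budgets 1k/5k/20k.

    Expensive (tens of seconds); shared by parameter-recovery, recall and
    acceptance tests.
    """
    out = {}
    for budget, seed in ((1000, 11), (5000, 12), (20000, 13)):
        acq = AcquisitionConfig(photons_per_pixel=float(budget), seed=seed)
        cube = render_decay_cube(disk_scene, acq)
        fmap = filter_fits(fit_cube(cube, FitOptions()))
        out[budget] = (cube, fmap)
    return out


def tm_relative_errors(scene, fmap):
    truth = scene.ground_truth
    tm_fit = fmap.tm[truth["y"].to_numpy(), truth["x"].to_numpy()]
    expected = truth["expected_tm_ps"].to_numpy()
    return np.abs(tm_fit - expected) / expected
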