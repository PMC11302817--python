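import numpy as np
import pytest

from cylqa.simulate import (BeamConfig, DetectorGeometry, ErrorSpec,
                            SimConfig, generate_dataset, render_plan)


@pytest.fixture(scope="session")
def geometry() -> DetectorGeometry:
    return DetectorGeometry()


@pytest.fixture(scope="session")
def simple_beams() -> list[BeamConfig]:
    return [
        BeamConfig(gantry_deg=40.0, collimator_deg=20.0, mu_weight=1.0,
                   apertures=((0.0, 0.0, 25.0, 25.0), (-30.0, 10.0, 10.0, 15.0))),
        BeamConfig(gantry_deg=180.0, collimator_deg=75.0, mu_weight=0.8,
                   apertures=((10.0, -5.0, 20.0, 30.0),)),
    ]


@pytest.fixture(scope="session")
def normal_map(simple_beams, geometry):
    return render_plan(simple_beams, geometry, ErrorSpec.normal())


@pytest.fixture(scope="session")
def tiny_dataset():
    """Balanced 5-class noise-free dataset, 4 plans per class."""
    return generate_dataset(SimConfig(n_per_class=4, noise_sigma=0.0, seed=7))


@pytest.fixture(scope="session")
def default_dataset():
    """The default-size dataset (300 plans) used by bookkeeping tests."""
    return generate_dataset(SimConfig(n_per_class=60, seed=11))


def random_map(rng: np.random.Generator, geometry: DetectorGeometry,
               smooth: bool = True):
    """A positive random dose map, optionally smoothed to look field-like."""
    from scipy.ndimage import gaussian_filter
    from cylqa.simulate import DetectorMap
    vals = rng.random(geometry.shape)
    if smooth:
        vals = gaussian_filter(vals, sigma=1.5, mode=("nearest", "wrap"))
    return DetectorMap(vals, geometry)
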