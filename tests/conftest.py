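import numpy as np
import pytest

from slimspore.config import Config
from slimspore.simulate import CellGeometry, NoiseModel, simulate_stage_image


@pytest.fixture(scope="session")
def config() -> Config:
    return Config()


@pytest.fixture(scope="session")
def stage_images():
    """One noise-free two-channel rendering per sporulation stage."""
    out = {}
    for stage in ("I", "II_i", "II_ii", "II_iii", "III"):
        geom = CellGeometry(length_um=2.4, stage=stage)
        stacks, truth = simulate_stage_image(geom, seed=11, noise=None,
                                             n_average_frames=1)
        out[stage] = (geom, stacks)
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
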