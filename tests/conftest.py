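import numpy as np
import pytest

from pemscat import (build_geometry, build_lyso_table, run_study)


@pytest.fixture(scope="session")
def xs():
    return build_lyso_table()


@pytest.fixture(scope="session")
def geom_mono():
    return build_geometry("monolithic")


@pytest.fixture(scope="session")
def geom_pix():
    return build_geometry("pixelated")


@pytest.fixture(scope="session")
def small_cuboid_mono(xs):
    """A modest uniform-cuboid acquisition shared by analysis unit tests."""
    return run_study("monolithic", "cuboid", 120_000, seed=20240229, xs=xs)


@pytest.fixture(scope="session")
def small_cuboid_pix(xs):
    return run_study("pixelated", "cuboid", 120_000, seed=20240229, xs=xs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
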