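import numpy as np
import pytest

from wolfroads.synthetic_data import (
    LandscapeConfig,
    WolfConfig,
    generate_landscape,
    make_study,
)


@pytest.fixture(scope="session")
def landscape():
    """One 20x20 km landscape shared by the geometry-heavy tests."""
    return generate_landscape(LandscapeConfig(extent_km=(20.0, 20.0), seed=42))


@pytest.fixture(scope="session")
def small_study():
    """A compact multi-territory study reused by the analysis tests."""
    return make_study(
        n_territories=4,
        n_datasets=8,
        landscape_cfg=LandscapeConfig(extent_km=(20.0, 20.0)),
        wolf_cfg=WolfConfig(study_days=14),
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
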