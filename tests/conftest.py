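import numpy as np
import pandas as pd
import pytest

from wingcrypsis.simulate import (
    CohortSimParams,
    WingSimParams,
    generate_cohort_series,
    generate_wing_image,
)


@pytest.fixture(scope="session")
def noiseless_wings():
    """One zero-noise wing per developmental temperature."""
    params = WingSimParams(pixel_noise_sd=0.0, seed=11)
    return {td: generate_wing_image(params, td) for td in (19, 27)}


@pytest.fixture(scope="session")
def small_cohorts():
    """A small full-factorial cohort table with the default effect structure."""
    return generate_cohort_series(CohortSimParams(n_cohorts_per_cell=2, seed=5))


@pytest.fixture()
def uniform_image():
    img = np.empty((20, 30, 3))
    img[:] = (0.5, 0.325, 0.2)
    return img
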