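import numpy as np
import pytest

from pedovox.grids import STANDARD_INCREMENTS
from pedovox.synthetic import (CoefficientLink, generate_dem, make_coefficient_truth,
                               sample_plots, simulate_profiles)
from pedovox.terrain import SmoothingConfig, derive_base_attributes, smooth_multiscale, standardize

MIDS = STANDARD_INCREMENTS.mid_depths_cm


@pytest.fixture(scope="session")
def small_dem():
    return generate_dem((40, 40), seed=7)


@pytest.fixture(scope="session")
def small_stack(small_dem):
    base = derive_base_attributes(small_dem)
    stack = smooth_multiscale(base, SmoothingConfig(radii=(1, 2, 4)))
    stack, _ = standardize(stack)
    return stack


@pytest.fixture(scope="session")
def small_exp_truth(small_stack):
    links = {
        "c1": CoefficientLink(intercept=1.1, weights={"twi_r2": 0.2, "slope_r2": -0.1},
                              noise_scale=0.0, clip_range=(0.8, 1.55)),
        "c2": CoefficientLink(intercept=-0.035, weights={"slope_r4": -0.005},
                              noise_scale=0.0, clip_range=(-0.045, -0.025)),
    }
    return make_coefficient_truth(small_stack, "exp", links, seed=3)


@pytest.fixture(scope="session")
def small_plots(small_dem):
    return sample_plots(small_dem, n_total=24, n_bd=18, seed=5)


@pytest.fixture(scope="session")
def noiseless_soc(small_exp_truth, small_plots):
    return simulate_profiles(small_exp_truth, small_plots, noise_sd=0.0, seed=9,
                             property_name="SOC", units="%", value_bounds=(0.35, 5.06))
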