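import numpy as np
import pytest

from swaysync.datatypes import ARModel
from swaysync.synthetic_data import SynthSpec, make_condition_coefficients


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def oo_model():
    """Ground-truth symmetric bidirectional AR(3) model at 5 Hz."""
    coeffs = make_condition_coefficients("OO")
    return ARModel(
        order=3,
        coeffs=coeffs,
        noise_var=(1.0, 1.0),
        residuals=np.zeros((2, 10)),
        fs=5.0,
        aic=0.0,
        n_obs=10,
    )


@pytest.fixture
def one_lag_model():
    """The hand-checkable one-lag model A1 = [[0.5, 0.3], [0, 0.5]]."""
    return ARModel(
        order=1,
        coeffs=np.array([[[0.5, 0.3], [0.0, 0.5]]]),
        noise_var=(1.0, 1.0),
        residuals=np.zeros((2, 10)),
        fs=5.0,
        aic=0.0,
        n_obs=10,
    )


@pytest.fixture
def small_spec():
    """A fast, small synthetic study (single axis, short roster)."""
    return SynthSpec(n_pairs=3, n_trials_per_condition=2, axes=("AP",), seed=5)
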