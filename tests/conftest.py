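import warnings

import numpy as np
import pytest

from reachgrasp import SynthConfig, generate_dataset
from reachgrasp.classifiers import HyperParams

warnings.filterwarnings("ignore", message="Precision loss occurred")


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic subject: 5 grasp types, 30 trials each."""
    return generate_dataset(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A light 3-class dataset for fast pipeline tests."""
    cfg = SynthConfig(
        classes=("precision_disk", "palm_pinch", "lateral"),
        n_trials_per_class=10,
        trial_length_s=3.0,
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def fast_hp():
    """Reduced hyper-parameter grids keeping experiments quick."""
    return HyperParams(
        svm_C=(1.0, 10.0),
        svm_gamma=(0.001, 0.01),
        esn_n_neurons=(100,),
        esn_spectral_radius=(0.9,),
        esn_ridge_lambda=(1e-4, 1e-2),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
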