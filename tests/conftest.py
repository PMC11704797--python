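import warnings

import numpy as np
import pytest

from ppmsprog.benchmark import standard_benchmark
from ppmsprog.model import FitConfig, fit_progression_model


@pytest.fixture(scope="session")
def benchmark():
    """Standard 4-marker recovery benchmark: (cohort, truth, specs, traj)."""
    return standard_benchmark(seed=11)


@pytest.fixture(scope="session")
def benchmark_model(benchmark):
    """Progression model fitted once on the standard benchmark."""
    cohort, truth, specs, traj = benchmark
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_progression_model(cohort, specs, FitConfig())
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
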