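import numpy as np
import pytest

from fiberpack import (
    GammaDiameterModel,
    PackingConfig,
    build_population,
    run_packing,
)


@pytest.fixture(scope="session")
def small_run():
    """A small converged packing shared by metrics/experiment tests.

    150 axons, mu=3 um, sigma2=1 um^2, zero gap, 5000 iterations: enough to
    jam the core of the cloud and support a valid interior analysis mask.
    """
    model = GammaDiameterModel(mu=3.0, sigma2=1.0)
    population = build_population(model.sample(150, seed=7))
    config = PackingConfig(iter_max=5000, trace_every=1000, seed=7)
    state, trace = run_packing(population, config)
    return population, state, trace


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
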