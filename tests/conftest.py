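import numpy as np
import pytest

import mixtwice as mt


@pytest.fixture(scope="session")
def allnull_study():
    """m=2000 fully null units, n=10 per group, unit observation variance."""
    spec = mt.make_scenario("near_normal", pi0=1.0, m=2000, n_per_group=10)
    return mt.simulate_dataset(spec, seed=1)


@pytest.fixture(scope="session")
def allnull_fit(allnull_study):
    return mt.fit_mixtwice(allnull_study.stats)


@pytest.fixture(scope="session")
def tiny_study():
    """m=50 seeded study used for brute-force oracle comparisons."""
    spec = mt.make_scenario("near_normal", pi0=0.7, m=50, n_per_group=10)
    return mt.simulate_dataset(spec, seed=11)


@pytest.fixture(scope="session")
def fitted_posterior():
    """A moderate fitted study with its posterior table, shared across
    inference invariant tests."""
    spec = mt.make_scenario("near_normal", pi0=0.8, m=400, n_per_group=10)
    study = mt.simulate_dataset(spec, seed=5)
    fit = mt.fit_mixtwice(study.stats, K=8, L=5)
    post = mt.posterior_effects(fit, study.stats)
    return study, fit, post
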