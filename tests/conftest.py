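import warnings

import numpy as np
import pytest

from policyits.config import PopulationConfig
from policyits.scenarios import ExposureScenario, apply_scenario
from policyits.simulate import TruncationWarning, generate_population


def small_config(seed=0, **kw):
    """A reduced-scale population: same structure, fewer clusters."""
    defaults = dict(n_clusters=60, n_regions=6,
                    households_per_cluster_mean=8.0, seed=seed)
    defaults.update(kw)
    return PopulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_records():
    """One full-scale generated population (shared across tests)."""
    cfg = PopulationConfig(seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", TruncationWarning)
        records, truth = generate_population(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def small_records():
    cfg = small_config(seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", TruncationWarning)
        records, truth = generate_population(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def simple_fit():
    """A converged random-intercept fit on a small covariate-free cohort."""
    from policyits.model import ModelSpec, MultilevelPoissonITS
    from policyits.recovery import recovery_config

    cfg = recovery_config(n_clusters=60, seed=12,
                          households_per_cluster=8.0)
    records, truth = generate_population(cfg)
    scenario = ExposureScenario.primary()
    inc, _ = apply_scenario(records, scenario)
    spec = ModelSpec(outcome="delivery",
                     fixed_terms=("time", "subsidy", "post_time"),
                     random_terms=("intercept",))
    model = MultilevelPoissonITS.from_records(inc, spec, scenario)
    res = model.fit(restarts=0)
    assert res.converged
    return cfg, inc, res
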