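import numpy as np
import pytest

from micdad import (
    SimConfig,
    StudyConfig,
    apply_micdad_population,
    assign_survey_ages,
    default_rates,
    run_study,
    simulate_population,
    summarize,
)
from micdad.cli import substreams

SEED = 1
FULL_N = 100_000
STUDY = StudyConfig(n_subpops=200, subpop_size=5000, eval_ages=(40.0, 60.0, 80.0), seed=SEED)


def simulate_surveyed(setting, seed=SEED, n=FULL_N):
    """Simulate a cohort, assign survey ages and apply the masking rule."""
    rates = default_rates(setting)
    rngs = substreams(seed)
    pop, transitions = simulate_population(
        SimConfig(n_individuals=n, seed=seed), rates, rng=rngs["simulation"]
    )
    surveyed = apply_micdad_population(pop, assign_survey_ages(pop, rngs["survey"]))
    return surveyed, transitions


def paired_study(setting, seed=SEED, n=FULL_N, config=STUDY):
    surveyed, transitions = simulate_surveyed(setting, seed=seed, n=n)
    results = run_study(surveyed, config, rng=substreams(seed)["sampling"])
    return results, summarize(results), transitions


@pytest.fixture(scope="session")
def high_rates():
    return default_rates("high")


@pytest.fixture(scope="session")
def low_rates():
    return default_rates("low")


@pytest.fixture(scope="session")
def high_surveyed():
    """Full-scale high-incidence cohort with survey ages and masking applied."""
    return simulate_surveyed("high")


@pytest.fixture(scope="session")
def low_surveyed():
    return simulate_surveyed("low")


@pytest.fixture(scope="session")
def high_study(high_surveyed):
    surveyed, transitions = high_surveyed
    results = run_study(surveyed, STUDY, rng=substreams(SEED)["sampling"])
    return results, summarize(results), transitions


@pytest.fixture(scope="session")
def low_study(low_surveyed):
    surveyed, transitions = low_surveyed
    results = run_study(surveyed, STUDY, rng=substreams(SEED)["sampling"])
    return results, summarize(results), transitions


@pytest.fixture()
def rng():
    return np.random.default_rng(20240103)
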