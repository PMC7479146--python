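import numpy as np
import pytest

from ringlife import mortality as mort
from ringlife import stand_simulator as ss
from ringlife import synthetic_data as sd


@pytest.fixture(scope="session")
def small_population():
    """A modest screened-size synthetic population with its site table."""
    return sd.generate_population(sd.SynthConfig(n_trees=600, n_sites=20, seed=42))


@pytest.fixture(scope="session")
def known_sample_10k():
    cfg = sd.KnownTradeoffConfig(a_true=np.log(400.0), b_true=-0.5, n=10_000, seed=123)
    return cfg, sd.generate_known_tradeoff_sample(cfg)


@pytest.fixture(scope="session")
def picea_trajectories():
    """Full-length black-spruce-like trajectories for the cohort simulator."""
    series, _ = sd.generate_population(sd.SynthConfig(n_trees=800, seed=3), full_length=True)
    return series


@pytest.fixture(scope="session")
def paired_runs(picea_trajectories):
    """Baseline + stimulated runs under size-dependent mortality, paired seeds."""
    cfg = ss.SimConfig(cohort_size=125, mortality=mort.DIAMETER_MORTALITY_DEFAULTS, seed=11)
    stim = ss.StimulusConfig()
    base = ss.run_simulation(picea_trajectories, cfg)
    treat = ss.run_simulation(picea_trajectories, cfg, stim)
    return cfg, stim, base, treat


@pytest.fixture(scope="session")
def paired_runs_age(picea_trajectories):
    """Same paired runs under age-dependent mortality (no trade-off)."""
    cfg = ss.SimConfig(cohort_size=125, mortality=mort.AGE_MORTALITY_DEFAULTS, seed=11)
    stim = ss.StimulusConfig()
    base = ss.run_simulation(picea_trajectories, cfg)
    treat = ss.run_simulation(picea_trajectories, cfg, stim)
    return cfg, stim, base, treat
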