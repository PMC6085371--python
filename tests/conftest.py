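import numpy as np
import pytest

from socflux.bayes import MCMCConfig, ObservationSet, StudyDesign

#: ground-truth interactive parameters used by several fixtures: substrate
#: turning over in weeks, old SOC in years, priming sized like the incubation
#: literature's tens-of-percent CO2 increases
TRUTH = {"K_N": 0.05, "K_O": 2e-4, "r": 0.4, "K_p": 1e-3, "p": 1.0,
         "f_N": 0.01}
SOC = 10.0      # mg C g^-1 soil
ADDED = 1.0     # mg C g^-1 soil (10% of the stock)


def make_observations(truth=TRUTH, soc=SOC, added=ADDED, noise_cv=0.0,
                      seed=0, times=None, study_id="toy-1",
                      nc_category="none"):
    """Simulate a paired incubation from known truth and package it as an
    ObservationSet (increment-level multiplicative noise, SD column
    populated)."""
    if times is None:
        times = np.arange(7.0, 71.0, 7.0)
    shell = ObservationSet(
        study_id, soc=soc, added_c=added, nc_category=nc_category,
        series={nm: np.c_[times, np.zeros_like(times), np.ones_like(times)]
                for nm in ("old_control", "old_treatment", "new_treatment")})
    clean = StudyDesign("interactive", shell).modeled_series(truth, dt=0.05)
    rng = np.random.default_rng(seed)
    series = {}
    for nm, z in clean.items():
        if noise_cv > 0:
            inc = np.diff(z, prepend=0.0)
            noisy = np.maximum(inc * (1 + noise_cv * rng.standard_normal(inc.size)), 0.0)
            zn = np.cumsum(noisy)
        else:
            zn = z
        sd = np.maximum(noise_cv * zn, 0.01 * added)
        series[nm] = np.c_[times, zn, sd]
    return ObservationSet(study_id, soc=soc, added_c=added,
                          nc_category=nc_category, series=series)


@pytest.fixture(scope="session")
def toy_obs():
    """Noise-free synthetic incubation from the session truth."""
    return make_observations()


@pytest.fixture(scope="session")
def noisy_obs():
    """Same incubation with 5% increment noise."""
    return make_observations(noise_cv=0.05, seed=42)


@pytest.fixture(scope="session")
def short_mcmc():
    return MCMCConfig(n_iterations=4000, seed=7)


@pytest.fixture(scope="session")
def toy_chain(toy_obs, short_mcmc):
    """One short interactive-model fit shared across tests."""
    from socflux.bayes import run_mcmc

    return run_mcmc("interactive", toy_obs, short_mcmc)
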