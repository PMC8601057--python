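import numpy as np
import pytest
from hypothesis import settings

import ploveripm as pp

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return pp.SurveyDesign()


@pytest.fixture(scope="session")
def small_design():
    """A compact 3-region, 8-year design for fast end-to-end tests."""
    return pp.SurveyDesign(regions=("Texas", "New Mexico", "Oklahoma"),
                           first_year=2000, last_year=2007, n_grids=100)


@pytest.fixture(scope="session")
def small_scenario(small_design):
    return pp.SimulationScenario(
        design=small_design, availability="full", n_nests=12, n_marked=10,
        n_dates={"Texas": 3, "New Mexico": 2},
        n_grid_surveyed=15, n_distance_grids=3, n_distance_visits=2, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_scenario):
    bundle, state, demog = pp.simulate_bundle(small_scenario)
    return bundle, state, demog


def make_state(bundle, state, fill_eps_y=0.0):
    """LatentState for a simulated truth, with eps_y fields sized to the
    bundle's grouping."""
    from ploveripm.likelihood import eps_groups

    eps_y = {}
    for stream in ("survey", "grid", "distance"):
        _, n_groups = eps_groups(bundle, stream)
        eps_y[stream] = np.full(n_groups, fill_eps_y)
    return pp.LatentState(log_n=state.log_n, eps_2=state.eps_2,
                          eps_3=state.eps_3, eps_f=state.eps_f,
                          eps_C=state.eps_C, eps_y=eps_y)


@pytest.fixture(scope="session")
def paper_fit():
    """One desk-scale fit of the study-pattern scenario, shared by the
    calibration, convergence and post-fit analysis tests."""
    scenario = pp.SimulationScenario(seed=11)
    model, truth = pp.PloverIPM.from_scenario(scenario)
    config = pp.MCMCConfig(n_chains=4, n_iter=12_000, n_burn=2_000, thin=5,
                           seed=4)
    res = model.fit(config, n_latent_draws=200)
    return scenario, model, truth, res
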