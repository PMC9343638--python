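"""Shared synthetic fixtures. Everything is generated in-process from seeds;
the small scenario keeps unit tests fast, the strong scenario (module-scoped
in the acceptance tests) exercises the full study conditions."""

import numpy as np
import pytest

import fluoromap as fm


@pytest.fixture(scope="session")
def small_scenario() -> fm.SyntheticScenario:
    return fm.SyntheticScenario(
        seed=7,
        grid_shape=(60, 60),
        n_covariates=8,
        informative_indices=(0, 1, 2),
        n_wells=1200,
        duplicate_rate=0.1,
        n_countries=3,
        smoothness=6.0,
    )


@pytest.fixture(scope="session")
def small_stack(small_scenario):
    return fm.gen_covariate_rasters(small_scenario)


@pytest.fixture(scope="session")
def small_truth(small_scenario, small_stack):
    return fm.gen_truth_surface(small_stack, small_scenario)


@pytest.fixture(scope="session")
def small_raw(small_scenario, small_truth):
    return fm.gen_measurements(small_truth, small_scenario)


@pytest.fixture(scope="session")
def small_table(small_scenario, small_stack, small_raw):
    return fm.build_model_table(small_raw, small_stack)


@pytest.fixture(scope="session")
def small_model(small_scenario, small_table):
    cfg = fm.ForestConfig(n_trees=101, seed=7)
    return fm.train_balanced_forest(small_table, small_scenario.band_names, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
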