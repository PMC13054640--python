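"""Shared fixtures: one small synthetic study reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from ecostab import community, stability, synth


@pytest.fixture(scope="session")
def small_config() -> synth.GeneratorConfig:
    return synth.GeneratorConfig(
        seed=11, n_sites=2, n_experiments_per_site=2, n_plots=8, years=40
    )


@pytest.fixture(scope="session")
def bundle(small_config) -> synth.SyntheticBundle:
    return synth.generate_all(small_config)


@pytest.fixture(scope="session")
def properties(bundle) -> pd.DataFrame:
    clean, _ = community.clean_composition(bundle.composition)
    return community.community_properties(clean)


@pytest.fixture(scope="session")
def stability_table(bundle, properties) -> pd.DataFrame:
    stab, _ = stability.build_stability_table(bundle.biomass, bundle.catalog, properties)
    stab["experiment_uid"] = stab["site"] + ":" + stab["experiment"]
    stab["plot_uid"] = stab["experiment_uid"] + ":" + stab["plot"]
    stab["year"] = stab["event_year"]
    return stab


@pytest.fixture(scope="session")
def lrr_table(bundle, properties) -> pd.DataFrame:
    lrr, _ = stability.build_lrr_table(bundle.biomass, bundle.catalog, properties)
    lrr["experiment_uid"] = lrr["site"] + ":" + lrr["experiment"]
    lrr["plot_uid"] = lrr["experiment_uid"] + ":" + lrr["plot"]
    lrr["year"] = lrr["event_year"]
    return lrr


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
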