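import pytest

from iemscreen import (
    derive_sim_params_from_ri,
    fit_zscore_model,
    load_marker_groups,
    load_panel,
    load_signatures,
    simulate_reference_cohort,
)
from iemscreen.quantify import impute_below_lod


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def panel_map(panel):
    return {a.name: a for a in panel}


@pytest.fixture(scope="session")
def sim_params(panel):
    return derive_sim_params_from_ri(panel)


@pytest.fixture(scope="session")
def sim_params_map(sim_params):
    return {p.name: p for p in sim_params}


@pytest.fixture(scope="session")
def signatures():
    return load_signatures()


@pytest.fixture(scope="session")
def marker_groups():
    return load_marker_groups()


@pytest.fixture(scope="session")
def reference_296(sim_params):
    """Synthetic non-IEM reference cohort at the study's size."""
    return simulate_reference_cohort(sim_params, 296, seed=20)


@pytest.fixture(scope="session")
def reference_296_imputed(reference_296, panel):
    return impute_below_lod(reference_296, panel)


@pytest.fixture(scope="session")
def zscore_model(reference_296_imputed, panel):
    return fit_zscore_model(reference_296_imputed, panel)
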