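import numpy as np
import pytest

from pondscape import (
    EnsembleNicheModel,
    OccurrenceSet,
    SyntheticConfig,
    TrueSuitabilityModel,
    generate_climate_grids,
    sample_occurrences,
)


@pytest.fixture(scope="session")
def desk_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def coarse_climate(desk_config):
    """Current-scenario coarse climate rasters."""
    return generate_climate_grids(desk_config)["current"]


@pytest.fixture(scope="session")
def sharp_truth() -> TrueSuitabilityModel:
    """Logistic ground-truth niche occupying roughly a tenth of the area."""
    return TrueSuitabilityModel(
        {"clim_0": -6.0, "clim_1": 4.0, "clim_2": -3.0}, intercept=-8.0
    )


@pytest.fixture(scope="session")
def climate_ensemble(coarse_climate, sharp_truth):
    """A fitted climate-only ensemble on the desk-scale landscape."""
    pts = sample_occurrences(sharp_truth, coarse_climate, 300, seed=1)
    occ = OccurrenceSet("newt_a", pts)
    model = EnsembleNicheModel(
        coarse_climate, occ, n_pa=300, n_pa_sets=2, n_runs=2, seed=1
    )
    return model.fit()
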