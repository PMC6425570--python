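import numpy as np
import pytest

from pregtrends import (
    ExposureSurface,
    RateSurface,
    GROUPS,
)
from pregtrends.synthetic import (
    SyntheticWorldConfig,
    ObservationProcessConfig,
    generate_world,
    generate_observations,
)
from pregtrends.pipeline import (
    classify_all,
    abortion_data_from_frame,
    intention_data_from_frame,
)
from pregtrends.inference import build_model, fit


def random_surfaces(seed: int, n_countries: int = 3, n_periods: int = 4):
    """Random exposure/rate surfaces for accounting property tests."""
    rng = np.random.default_rng(seed)
    F = len(GROUPS)
    women = rng.uniform(1e3, 1e6, size=(F, n_countries, n_periods))
    births = rng.uniform(1e3, 1e5, size=(n_countries, n_periods))
    exposure = ExposureSurface(
        countries=[f"c{i}" for i in range(n_countries)],
        periods=list(range(1990, 1990 + 5 * n_periods, 5)),
        women=women,
        births=births,
    )
    rates = RateSurface(
        omega=rng.uniform(0.01, 0.4, size=(F, n_countries, n_periods)),
        alpha=rng.uniform(0.02, 0.7, size=(F, n_countries, n_periods)),
    )
    return exposure, rates


@pytest.fixture(scope="session")
def tiny_world():
    return generate_world(
        SyntheticWorldConfig(seed=7, n_regions=2, countries_per_region=3)
    )


@pytest.fixture(scope="session")
def tiny_observations(tiny_world):
    ab, it = generate_observations(tiny_world, ObservationProcessConfig(seed=8))
    obs, audit = classify_all(
        abortion_data_from_frame(ab),
        intention_data_from_frame(it),
        tiny_world.regions,
    )
    return obs, audit


@pytest.fixture(scope="session")
def tiny_posterior(tiny_world, tiny_observations):
    obs, _ = tiny_observations
    config = tiny_world.model_config(
        sampler={"method": "laplace", "draws": 300, "seed": 3}
    )
    model = build_model(obs, tiny_world.exposure, config, tiny_world.covariates)
    return fit(model)
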