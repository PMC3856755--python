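import numpy as np
import pandas as pd
import pytest

from trophicsdm.foodweb import LinkModelParams, PlantTraits, TrophicWeb
from trophicsdm.synthesize import SyntheticConfig, make_study


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    return make_study(SyntheticConfig(seed=11, n_plants=12, n_butterflies=14, n_sites=60))


def random_link_problem(seed: int, n_plants: int = 4, n_butterflies: int = 4):
    """Random web + parameters + traits for oracle comparisons."""
    rng = np.random.default_rng(seed)
    plants = [f"p{i}" for i in range(n_plants)]
    bflies = [f"b{j}" for j in range(n_butterflies)]
    traits = PlantTraits(
        pd.DataFrame(
            {"nitrogen": rng.normal(2, 1, n_plants), "avg_height": rng.normal(0.5, 0.2, n_plants)},
            index=plants,
        )
    )
    d = np.sort(np.abs(rng.normal(0, 1, 2)))[::-1]
    params = LinkModelParams(
        alpha=float(rng.normal()),
        beta_nitrogen=float(rng.normal()),
        beta_height=float(rng.normal()),
        delta=(float(d[0]), float(d[1])),
        plant_latents=pd.DataFrame(
            rng.normal(size=(n_plants, 2)), index=plants, columns=["v1", "v2"]
        ),
        butterfly_latents=pd.DataFrame(
            rng.normal(size=(n_butterflies, 2)), index=bflies, columns=["f1", "f2"]
        ),
    )
    web = TrophicWeb(
        plant_ids=plants,
        butterfly_ids=bflies,
        links=rng.integers(0, 2, (n_plants, n_butterflies)),
        mask=rng.integers(0, 2, (n_plants, n_butterflies)),
    )
    return web, params, traits


@pytest.fixture
def link_problem_factory():
    return random_link_problem
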