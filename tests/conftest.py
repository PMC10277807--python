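"""Shared fixtures: small synthetic worlds and a cached model fit."""

import numpy as np
import pandas as pd
import pytest

import dietscore as ds
from dietscore.strata import STRATUM_COLUMNS, strata_frame


@pytest.fixture(scope="session")
def small_world() -> ds.World:
    """2 regions x 2 countries, 3 factors incl. energy, 2 analysis years."""
    cfg = ds.WorldConfig(
        n_regions=2,
        countries_per_region=2,
        years=(1990, 2018),
        factors=(
            ds.Factor("fruit", "g/day"),
            ds.Factor("pufa", "%energy"),
            ds.Factor("energy", "kcal/day"),
        ),
        seed=42,
    )
    return ds.build_world(cfg)


@pytest.fixture(scope="session")
def small_records(small_world) -> pd.DataFrame:
    return ds.simulate_surveys(small_world, seed=7)


@pytest.fixture(scope="session")
def small_fit(small_world, small_records) -> ds.IntakeResults:
    """One cached MCMC fit shared by the tests that need a posterior."""
    model = ds.IntakeModel(
        small_records,
        small_world.region_of,
        small_world.covariates,
        small_world.weights,
    )
    return model.fit(seed=5)


def make_score_population(
    seed: int = 0,
    n_countries: int = 3,
    years: tuple[int, ...] = (1990, 2018),
    n_draws: int = 40,
    factors: tuple[str, ...] = ("fruit", "vegetables"),
) -> tuple[ds.DrawFrame, pd.DataFrame]:
    """A synthetic stratum-level intake DrawFrame plus matching weights.

    Built directly (no MCMC) for scoring and aggregation tests; draws are
    log-normal around stratum-specific means.
    """
    rng = np.random.default_rng(seed)
    sf = strata_frame()
    frames, weights = [], []
    for ci in range(n_countries):
        country = f"R1C{ci + 1}"
        for year in years:
            for factor in factors:
                idx = sf.copy()
                idx.insert(0, "year", year)
                idx.insert(0, "country", country)
                idx["factor"] = factor
                base = rng.lognormal(np.log(150), 0.3, size=len(sf))
                draws = base[:, None] * np.exp(
                    rng.normal(0, 0.05, size=(len(sf), n_draws))
                )
                frames.append(ds.DrawFrame(idx, draws))
            wblock = sf.copy()
            wblock.insert(0, "year", year)
            wblock.insert(0, "country", country)
            wblock["persons"] = rng.uniform(1e3, 1e5, size=len(sf))
            weights.append(wblock)
    from dietscore.draws import concat_drawframes

    return concat_drawframes(frames), pd.concat(weights, ignore_index=True)


@pytest.fixture()
def score_population():
    return make_score_population()
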