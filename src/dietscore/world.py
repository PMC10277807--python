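"""Synthetic world generator: regions, countries, true intake surfaces,
population weights and country-year covariates.

The generator produces a miniature version of the global frame the intake
model is designed for: countries nested in regions, 264 demographic strata
per country-year, and for every dietary factor a ground-truth surface of
stratum mean intakes built additively on the log scale from

* a global log-mean,
* mean-zero region and country random effects,
* additive sex / education / urbanicity effects,
* a smooth non-linear age curve evaluated at the 22 band midpoints,
* a country-specific linear time trend whose intercepts and slopes are
  correlated across countries.

Individual intakes within a stratum are log-normal around the stratum
mean; surveys observe noisy sample means of those individuals (see
:mod:`dietscore.surveys`).  Because the truth is recorded alongside the
simulated observations, every downstream stage can be tested for
parameter recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .strata import (
    AGE_BANDS,
    AGE_MIDPOINTS,
    EDUCATION_LEVELS,
    SEXES,
    STRATUM_COLUMNS,
    URBANICITY_LEVELS,
    strata_frame,
)

#: units treated as energy-relative: unchanged by energy standardization
RELATIVE_UNITS = ("%energy", "ratio")

VALID_UNITS = ("g/day", "servings/day", "mg/day", "kcal/day") + RELATIVE_UNITS


@dataclass(frozen=True)
class Factor:
    name: str
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r} for factor {self.name!r}")


#: desk-scale default factor set: the nine AHEI components plus total energy
DEFAULT_FACTORS: tuple[Factor, ...] = (
    Factor("fruit", "g/day"),
    Factor("vegetables", "g/day"),
    Factor("whole_grains", "g/day"),
    Factor("legumes_nuts", "g/day"),
    Factor("ssb", "g/day"),
    Factor("red_processed_meat", "g/day"),
    Factor("seafood_omega3", "mg/day"),
    Factor("pufa", "%energy"),
    Factor("sodium", "mg/day"),
    Factor("energy", "kcal/day"),
)

#: full set needed to score AHEI, DASH and MED together
SCORING_FACTORS: tuple[Factor, ...] = DEFAULT_FACTORS + (
    Factor("dairy", "g/day"),
    Factor("fish", "g/day"),
    Factor("mufa_sfa_ratio", "ratio"),
)

#: plausible population-typical intakes, natural units, used as the
#: default global means of the true surfaces
DEFAULT_GLOBAL_MEANS: dict[str, float] = {
    "fruit": 150.0,
    "vegetables": 220.0,
    "whole_grains": 60.0,
    "legumes_nuts": 45.0,
    "ssb": 120.0,
    "red_processed_meat": 80.0,
    "seafood_omega3": 150.0,
    "pufa": 5.5,
    "sodium": 3200.0,
    "energy": 2100.0,
    "dairy": 220.0,
    "fish": 40.0,
    "mufa_sfa_ratio": 1.2,
}
_FALLBACK_GLOBAL_MEAN = 100.0


@dataclass(frozen=True)
class WorldConfig:
    """Size and composition of the synthetic world.

    The default desk scale (3 regions x 4 countries each, 10 factors,
    4 years) keeps a full model fit in the minutes range while exercising
    every structural feature of the estimation problem.
    """

    n_regions: int = 3
    countries_per_region: int = 4
    years: tuple[int, ...] = (1990, 2000, 2010, 2018)
    factors: tuple[Factor, ...] = DEFAULT_FACTORS
    seed: int = 0
    # log-scale magnitudes of the true effects
    region_sd: float = 0.20
    country_sd: float = 0.12
    sex_sd: float = 0.08
    education_sd: float = 0.10
    urbanicity_sd: float = 0.08
    age_sd: float = 0.20
    slope_mean_sd: float = 0.004  # per year, across factors
    slope_sd: float = 0.002  # per year, across countries
    intercept_slope_corr: float = 0.3
    intra_sd: float = 0.50  # log-SD of individual intakes within a stratum
    covariate_noise_sd: float = 0.05
    global_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.countries_per_region < 1:
            raise ValueError("need at least one region and one country per region")
        if 1990 not in self.years or 2018 not in self.years:
            raise ValueError("years must include both analysis endpoints 1990 and 2018")
        names = [f.name for f in self.factors]
        if len(names) != len(set(names)):
            raise ValueError("duplicate factor names")
        if not (-1.0 <= self.intercept_slope_corr <= 1.0):
            raise ValueError("intercept_slope_corr must be in [-1, 1]")
        for name, mean in self.global_means.items():
            if not mean > 0:
                raise ValueError(
                    f"global mean for factor {name!r} must be strictly positive, "
                    f"got {mean}"
                )

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def factor_units(self) -> dict[str, str]:
        return {f.name: f.unit for f in self.factors}

    @property
    def regions(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.n_regions)]

    @property
    def countries(self) -> list[str]:
        return [
            f"R{i + 1}C{j + 1}"
            for i in range(self.n_regions)
            for j in range(self.countries_per_region)
        ]

    @property
    def region_of(self) -> dict[str, str]:
        return {c: c.split("C")[0] for c in self.countries}

    def global_mean(self, factor: str) -> float:
        if factor in self.global_means:
            return self.global_means[factor]
        return DEFAULT_GLOBAL_MEANS.get(factor, _FALLBACK_GLOBAL_MEAN)


YEAR_CENTER = 2004.0  # centering year for time trends


def _smooth_age_curve(rng: np.random.Generator, sd: float) -> np.ndarray:
    """A smooth mean-zero curve over the 22 age-band midpoints.

    Values are drawn at five anchor ages and joined with a monotone cubic
    interpolant, so the curve is non-linear but smooth enough for a
    natural cubic spline with knots at every third midpoint to represent.
    """
    mids = np.array([AGE_MIDPOINTS[a] for a in AGE_BANDS])
    anchors = np.array([0.5, 12.5, 37.5, 67.5, 97.5])
    vals = rng.normal(0.0, sd, size=anchors.size)
    curve = PchipInterpolator(anchors, vals)(mids)
    return curve - curve.mean()


@dataclass
class FactorSurface:
    """Ground truth for one dietary factor."""

    factor: str
    unit: str
    global_log_mean: float
    region_effects: dict[str, float]
    country_effects: dict[str, float]
    sex_effects: dict[str, float]
    education_effects: dict[str, float]
    urbanicity_effects: dict[str, float]
    age_curve: dict[str, float]
    country_slopes: dict[str, float]  # log units per year
    intercept_slope_corr: float
    intra_sd: float

    def log_mean(self, country: str, year: int, sex: str, age_group: str,
                 education: str, urbanicity: str) -> float:
        region = country.split("C")[0]
        return (
            self.global_log_mean
            + self.region_effects[region]
            + self.country_effects[country]
            + self.sex_effects[sex]
            + self.education_effects[education]
            + self.urbanicity_effects[urbanicity]
            + self.age_curve[age_group]
            + self.country_slopes[country] * (year - YEAR_CENTER)
        )

    def stratum_log_means(self, country: str, year: int) -> np.ndarray:
        """True log mean intake for the 264 strata in canonical order."""
        sf = strata_frame()
        base = (
            self.global_log_mean
            + self.region_effects[country.split("C")[0]]
            + self.country_effects[country]
            + self.country_slopes[country] * (year - YEAR_CENTER)
        )
        return (
            base
            + sf["sex"].map(self.sex_effects).to_numpy()
            + sf["education"].map(self.education_effects).to_numpy()
            + sf["urbanicity"].map(self.urbanicity_effects).to_numpy()
            + sf["age_group"].map(self.age_curve).to_numpy()
        )

    def stratum_means(self, country: str, year: int) -> np.ndarray:
        return np.exp(self.stratum_log_means(country, year))


@dataclass
class World:
    """A fully generated synthetic world: truth, weights and covariates."""

    config: WorldConfig
    surfaces: dict[str, FactorSurface]
    weights: pd.DataFrame  # country, year, stratum columns, persons
    covariates: pd.DataFrame  # factor, country, year, value
    meta: dict = field(default_factory=dict)

    @property
    def region_of(self) -> dict[str, str]:
        return self.config.region_of

    def true_log_means(self, factor: str) -> pd.DataFrame:
        """Ground-truth stratum log means for every country-year (long)."""
        surf = self.surfaces[factor]
        sf = strata_frame()
        rows = []
        for country in self.config.countries:
            for year in self.config.years:
                block = sf.copy()
                block.insert(0, "year", year)
                block.insert(0, "country", country)
                block["true_log_mean"] = surf.stratum_log_means(country, year)
                rows.append(block)
        out = pd.concat(rows, ignore_index=True)
        out.insert(2, "factor", factor)
        return out


def _make_weights(config: WorldConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Person counts for all 264 strata of every country-year.

    Shares follow simple demographic regularities: a declining age
    pyramid, a near-even sex split, country-specific education mixes and
    an urban share that rises over time.
    """
    sf = strata_frame()
    mids = sf["age_group"].map(AGE_MIDPOINTS).to_numpy()
    blocks = []
    for country in config.countries:
        total = float(np.exp(rng.normal(np.log(5e6), 0.5)))
        edu = rng.dirichlet(np.array([30.0, 45.0, 25.0]))
        edu_share = dict(zip(EDUCATION_LEVELS, edu))
        urban0 = float(rng.uniform(0.35, 0.65))
        female = float(rng.uniform(0.49, 0.51))
        aging = float(rng.uniform(0.015, 0.03))
        for year in config.years:
            urban = min(0.9, urban0 + 0.004 * (year - 1990))
            age_w = np.exp(-aging * mids)
            share = (
                age_w / age_w.sum() * len(AGE_BANDS) / len(sf)
                * np.where(sf["sex"] == "female", 2 * female, 2 * (1 - female))
                * sf["education"].map(edu_share).to_numpy() * len(EDUCATION_LEVELS)
                * np.where(sf["urbanicity"] == "urban", 2 * urban, 2 * (1 - urban))
            )
            block = sf.copy()
            block.insert(0, "year", year)
            block.insert(0, "country", country)
            block["persons"] = total * share / share.sum()
            blocks.append(block)
    return pd.concat(blocks, ignore_index=True)


def _make_surface(
    factor: Factor, config: WorldConfig, rng: np.random.Generator
) -> FactorSurface:
    mean = config.global_mean(factor.name)
    # correlated country intercepts and slopes
    corr = config.intercept_slope_corr
    cov = np.array(
        [
            [config.country_sd**2, corr * config.country_sd * config.slope_sd],
            [corr * config.country_sd * config.slope_sd, config.slope_sd**2],
        ]
    )
    n_c = len(config.countries)
    cs = rng.multivariate_normal(np.zeros(2), cov, size=n_c)
    cs -= cs.mean(axis=0)  # mean-zero country effects by construction
    slope0 = rng.normal(0.0, config.slope_mean_sd)
    region_eff = rng.normal(0.0, config.region_sd, size=config.n_regions)
    region_eff -= region_eff.mean()
    sex = rng.normal(0.0, config.sex_sd)
    edu = rng.normal(0.0, config.education_sd, size=3)
    edu -= edu.mean()
    urb = rng.normal(0.0, config.urbanicity_sd)
    return FactorSurface(
        factor=factor.name,
        unit=factor.unit,
        global_log_mean=float(np.log(mean)),
        region_effects=dict(zip(config.regions, region_eff)),
        country_effects=dict(zip(config.countries, cs[:, 0])),
        sex_effects={"male": -sex / 2, "female": sex / 2},
        education_effects=dict(zip(EDUCATION_LEVELS, edu)),
        urbanicity_effects={"urban": urb / 2, "rural": -urb / 2},
        age_curve=dict(zip(AGE_BANDS, _smooth_age_curve(rng, config.age_sd))),
        country_slopes=dict(zip(config.countries, slope0 + cs[:, 1])),
        intercept_slope_corr=corr,
        intra_sd=config.intra_sd,
    )


def _make_covariates(
    config: WorldConfig, surfaces: dict[str, FactorSurface], rng: np.random.Generator
) -> pd.DataFrame:
    """Country-year covariates emulating food availability series.

    The covariate tracks the country-year deviation of the national log
    mean from the global log mean, plus observation noise — the role FAO
    food-balance availability plays for real intakes.
    """
    rows = []
    for name, surf in surfaces.items():
        for country in config.countries:
            region = country.split("C")[0]
            for year in config.years:
                signal = (
                    surf.region_effects[region]
                    + surf.country_effects[country]
                    + surf.country_slopes[country] * (year - YEAR_CENTER)
                )
                rows.append(
                    (name, country, year, signal + rng.normal(0, config.covariate_noise_sd))
                )
    return pd.DataFrame(rows, columns=["factor", "country", "year", "value"])


def build_world(config: WorldConfig) -> World:
    """Generate the full synthetic world deterministically from the seed."""
    ss = np.random.SeedSequence(config.seed)
    s_surf, s_weights, s_cov = ss.spawn(3)
    rng_surf = np.random.default_rng(s_surf)
    surfaces = {f.name: _make_surface(f, config, rng_surf) for f in config.factors}
    for name, surf in surfaces.items():
        for country in config.countries:
            for year in (min(config.years), max(config.years)):
                lm = surf.stratum_log_means(country, year)
                if not np.all(np.isfinite(lm)):
                    raise ValueError(
                        f"non-finite implied mean for factor {name!r}, "
                        f"country {country}, year {year}"
                    )
    weights = _make_weights(config, np.random.default_rng(s_weights))
    covariates = _make_covariates(config, surfaces, np.random.default_rng(s_cov))
    meta = {
        "seed": config.seed,
        "n_regions": config.n_regions,
        "countries_per_region": config.countries_per_region,
        "years": list(config.years),
        "factors": {f.name: f.unit for f in config.factors},
    }
    return World(config, surfaces, weights, covariates, meta)
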