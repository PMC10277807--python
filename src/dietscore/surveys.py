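"""Survey simulation: noisy, biased observations of the true intake surface.

A survey observes, for each demographic cell it stratifies, the sample
mean and SD of n individual intakes.  Individuals are log-normal around
the stratum's true mean; the assessment method multiplies the target mean
by a factor-specific bias; surveys also carry a survey-level log-normal
shift (between-survey noise) that is larger for questionnaire-based
methods and for non-representative surveys — the overdispersion the
estimation model has to absorb.

Collapsed surveys (e.g. no education breakdown) report cells that pool
several base strata; pooled means are person-weighted across the
constituent strata, mirroring how such surveys sample people.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strata import COLLAPSED, STRATUM_COLUMNS, strata_frame
from .world import World

METHODS = ("24hr_recall", "FFQ", "DHS", "HBS")

#: placeholder multiplicative biases per method (the magnitude of real
#: survey-method biases is unknown; these are design defaults, not estimates)
DEFAULT_METHOD_BIAS: dict[str, float] = {
    "24hr_recall": 1.0,
    "FFQ": 0.92,
    "DHS": 0.85,
    "HBS": 1.15,
}

#: between-survey log-SD by method; non-representative surveys add 0.10
#: in quadrature
DEFAULT_METHOD_NOISE: dict[str, float] = {
    "24hr_recall": 0.0,
    "FFQ": 0.03,
    "DHS": 0.08,
    "HBS": 0.12,
}
NONREP_EXTRA_NOISE = 0.10


def unit_biases() -> dict[str, float]:
    """Bias-free method map (all multipliers 1.0)."""
    return {m: 1.0 for m in METHODS}


@dataclass(frozen=True)
class SurveyDesign:
    """Plan for one survey: where, when, how, and how finely stratified."""

    survey_id: str
    country: str
    year: int
    method: str = "24hr_recall"
    representative: bool = True
    n_per_stratum: int = 25
    collapsed: tuple[str, ...] = ()  # subset of {"education", "urbanicity"}

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_per_stratum < 1:
            raise ValueError("n_per_stratum must be >= 1")
        bad = set(self.collapsed) - {"education", "urbanicity"}
        if bad:
            raise ValueError(f"cannot collapse dimensions {sorted(bad)}")


SURVEY_COLUMNS = [
    "survey_id", "country", "year", "method", "representative",
    "sex", "age_group", "education", "urbanicity",
    "factor", "observed_mean", "observed_sd", "n",
]


def default_design(world: World) -> list[SurveyDesign]:
    """A survey plan covering every method, representativeness value and
    at least one collapsed-stratum survey per country set."""
    cfg = world.config
    designs: list[SurveyDesign] = []
    years = sorted(cfg.years)
    mid_year = years[len(years) // 2]
    for ci, country in enumerate(cfg.countries):
        for year in years:
            designs.append(
                SurveyDesign(f"{country}-{year}-R24", country, year, "24hr_recall")
            )
        for year in years[ci % 2 :: 2]:  # FFQs on alternating years
            designs.append(
                SurveyDesign(f"{country}-{year}-FFQ", country, year, "FFQ")
            )
        designs.append(
            SurveyDesign(
                f"{country}-{mid_year}-DHS", country, mid_year, "DHS",
                representative=False, collapsed=("education",),
            )
        )
        if ci % cfg.countries_per_region == 0:  # one HBS per region
            designs.append(
                SurveyDesign(
                    f"{country}-{years[0]}-HBS", country, years[0], "HBS",
                    representative=False, collapsed=("education", "urbanicity"),
                )
            )
    return designs


def _pool_collapsed(
    cells: pd.DataFrame, persons: np.ndarray, m: np.ndarray, v: np.ndarray,
    n: int, collapsed: tuple[str, ...],
) -> pd.DataFrame:
    """Person-weighted pooling of base-stratum sample moments."""
    keep = [c for c in STRATUM_COLUMNS if c not in collapsed]
    df = cells.copy()
    df["_w"] = persons
    df["_m"] = m
    df["_v"] = v
    out = []
    for key, grp in df.groupby(keep, sort=False):
        w = grp["_w"].to_numpy()
        w = w / w.sum() if w.sum() > 0 else np.full(len(grp), 1.0 / len(grp))
        mean = float(w @ grp["_m"].to_numpy())
        var = float(w @ (grp["_v"].to_numpy() + grp["_m"].to_numpy() ** 2) - mean**2)
        row = dict(zip(keep, key if isinstance(key, tuple) else (key,)))
        for dim in collapsed:
            row[dim] = COLLAPSED
        row.update(observed_mean=mean, observed_sd=np.sqrt(max(var, 0.0)),
                   n=n * len(grp))
        out.append(row)
    return pd.DataFrame(out)


def simulate_surveys(
    world: World,
    designs: list[SurveyDesign] | None = None,
    method_biases: dict[str, float] | dict[str, dict[str, float]] | None = None,
    method_noise: dict[str, float] | None = None,
    seed: int = 1,
) -> pd.DataFrame:
    """Simulate survey records for every design and every world factor.

    ``method_biases`` maps method -> multiplier, or method -> {factor:
    multiplier} for factor-specific biases.  Deterministic given ``seed``.
    """
    if designs is None:
        designs = default_design(world)
    biases = DEFAULT_METHOD_BIAS if method_biases is None else method_biases
    noise = DEFAULT_METHOD_NOISE if method_noise is None else method_noise
    cfg = world.config
    known = set(cfg.countries)
    for d in designs:
        if d.country not in known:
            raise ValueError(f"design {d.survey_id!r} references unknown country {d.country!r}")
        if d.year not in cfg.years:
            raise ValueError(f"design {d.survey_id!r} references unknown year {d.year}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sf = strata_frame()
    wtab = world.weights.set_index(["country", "year"] + STRATUM_COLUMNS)["persons"]

    def bias_for(method: str, factor: str) -> float:
        b = biases.get(method, 1.0)
        if isinstance(b, dict):
            return float(b.get(factor, 1.0))
        return float(b)

    blocks: list[pd.DataFrame] = []
    for d in designs:
        persons = wtab.loc[d.country, d.year].reindex(
            pd.MultiIndex.from_frame(sf)
        ).to_numpy()
        tau = float(noise.get(d.method, 0.0))
        if not d.representative:
            tau = float(np.hypot(tau, NONREP_EXTRA_NOISE))
        for fname, surf in world.surfaces.items():
            true_means = surf.stratum_means(d.country, d.year)
            shift = float(np.exp(rng.normal(0.0, tau))) if tau > 0 else 1.0
            target = true_means * bias_for(d.method, fname) * shift
            sd = surf.intra_sd
            mu = np.log(target) - sd**2 / 2.0
            z = rng.standard_normal((len(sf), d.n_per_stratum))
            x = np.exp(mu[:, None] + sd * z)
            m = x.mean(axis=1)
            if d.n_per_stratum > 1:
                v = x.var(axis=1, ddof=1)
            else:
                v = np.zeros(len(sf))
            if d.collapsed:
                block = _pool_collapsed(sf, persons, m, v, d.n_per_stratum, d.collapsed)
            else:
                block = sf.copy()
                block["observed_mean"] = m
                block["observed_sd"] = np.sqrt(v)
                block["n"] = d.n_per_stratum
            block.insert(0, "representative", d.representative)
            block.insert(0, "method", d.method)
            block.insert(0, "year", d.year)
            block.insert(0, "country", d.country)
            block.insert(0, "survey_id", d.survey_id)
            block["factor"] = fname
            blocks.append(block[SURVEY_COLUMNS])
    records = pd.concat(blocks, ignore_index=True)
    records.attrs["seed"] = seed
    return records
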