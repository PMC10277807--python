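"""Scoring rules, empirical cutpoints and pattern totals."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import lognorm

import dietscore as ds
from dietscore.draws import DrawFrame
from dietscore.scores import (
    QUINTILE_Q,
    score_component_linear,
    score_component_median,
    score_component_quintile,
)
from dietscore.strata import STRATUM_COLUMNS, strata_frame

AHEI = ds.load_definition("ahei")
DASH = ds.load_definition("dash")
MED = ds.load_definition("med")


# -- linear components --------------------------------------------------
@pytest.mark.parametrize(
    "intake,worst,optimal,direction,expected",
    [
        (0.0, 0.0, 4.0, "healthy", 0.0),
        (4.0, 0.0, 4.0, "healthy", 10.0),
        (6.0, 0.0, 4.0, "healthy", 10.0),  # clamped above optimal
        (2.0, 0.0, 4.0, "healthy", 5.0),  # linear midpoint
        (0.0, 1.0, 0.0, "unhealthy", 10.0),  # SSB at zero
        (0.5, 1.0, 0.0, "unhealthy", 5.0),  # mirrored linear
        (2.0, 1.0, 0.0, "unhealthy", 0.0),  # clamped beyond worst
    ],
)
def test_linear_component_scoring(intake, worst, optimal, direction, expected):
    assert score_component_linear(np.array([intake]), worst, optimal, direction)[0] == expected


def test_negative_intake_is_contract_violation():
    with pytest.raises(ValueError, match="negative"):
        score_component_linear(np.array([-1.0]), 0.0, 4.0, "healthy")


# -- quintile and median rules -----------------------------------------
def test_five_equal_strata_get_distinct_quintile_points():
    b = ds.weighted_quantile(np.arange(1.0, 6.0), np.ones(5), QUINTILE_Q)
    pts = score_component_quintile(np.arange(1.0, 6.0), b, "healthy")
    assert list(pts) == [1, 2, 3, 4, 5]
    rev = score_component_quintile(np.arange(1.0, 6.0), b, "unhealthy")
    assert list(rev) == [5, 4, 3, 2, 1]


def test_quantile_ties_take_lower_quintile():
    b = np.array([1.0, 2.0, 3.0, 4.0])
    assert score_component_quintile(np.array([2.0]), b, "healthy")[0] == 2
    assert score_component_quintile(np.array([2.0]), b, "unhealthy")[0] == 4
    assert score_component_median(np.array([5.0]), 5.0, "healthy")[0] == 0
    assert score_component_median(np.array([5.0]), 5.0, "unhealthy")[0] == 0


def test_quintile_boundaries_match_lognormal_theory():
    """Equal-weight empirical quintiles of a large log-normal sample agree
    with the distribution's closed-form quantiles."""
    rng = np.random.default_rng(4)
    vals = rng.lognormal(np.log(100), 0.4, size=20_000)
    b = np.asarray(ds.weighted_quantile(vals, np.ones_like(vals), QUINTILE_Q))
    theory = lognorm.ppf(QUINTILE_Q, s=0.4, scale=100)
    np.testing.assert_allclose(b, theory, rtol=0.02)


# -- population scoring -------------------------------------------------
def population_frame(factors, seed=0, n_draws=1, year=2018, scale=None):
    """All 264 strata of two countries with log-normal stratum intakes."""
    rng = np.random.default_rng(seed)
    sf = strata_frame()
    frames, weights = [], []
    for country in ("R1C1", "R1C2"):
        for factor in factors:
            idx = sf.copy()
            idx.insert(0, "year", year)
            idx.insert(0, "country", country)
            idx["factor"] = factor
            base = rng.lognormal(np.log((scale or {}).get(factor, 100.0)), 0.4, len(sf))
            frames.append(DrawFrame(idx, np.tile(base[:, None], (1, n_draws))))
        wblock = sf.copy()
        wblock.insert(0, "year", year)
        wblock.insert(0, "country", country)
        wblock["persons"] = rng.uniform(1e3, 1e4, len(sf))
        weights.append(wblock)
    from dietscore.draws import concat_drawframes

    return concat_drawframes(frames), pd.concat(weights, ignore_index=True)


def set_stratum(frame, stratum_row, values):
    """Overwrite one stratum's intakes (all draws) per factor."""
    idx = frame.index
    for factor, val in values.items():
        m = (idx["factor"] == factor).to_numpy()
        for col, v in stratum_row.items():
            m &= (idx[col] == v).to_numpy()
        assert m.sum() == 1
        frame.draws[m] = val
    return frame


STRATUM = {
    "country": "R1C1", "year": 2018, "sex": "male", "age_group": "30-34",
    "education": "<6y", "urbanicity": "urban",
}


def test_ahei_all_optimal_scores_100():
    factors = AHEI.factors
    frame, _ = population_frame(factors)
    optimal = {}
    for c in AHEI.components:
        optimal[c.factor] = c.optimal
    set_stratum(frame, STRATUM, optimal)
    totals = ds.score_strata(frame, AHEI)
    sub = totals.select(**{k: v for k, v in STRATUM.items()})
    assert sub.draws[0, 0] == pytest.approx(100.0, abs=1e-12)


def test_ahei_rescale_is_exactly_100_over_90():
    frame, _ = population_frame(AHEI.factors, seed=3)
    totals, comps = ds.score_strata(frame, AHEI, keep_components=True)
    sums = np.zeros_like(totals.draws)
    for comp in AHEI.components:
        sums += comps.select(component=comp.factor).draws
    np.testing.assert_allclose(totals.draws, sums * (100.0 / 90.0), rtol=1e-14)
    assert (totals.draws >= 0).all() and (totals.draws <= 100).all()


def test_dash_extremes_score_40_and_8():
    frame, weights = population_frame(DASH.factors, seed=5)
    best = {c.factor: (1e6 if c.direction == "healthy" else 0.0) for c in DASH.components}
    worst = {c.factor: (0.0 if c.direction == "healthy" else 1e6) for c in DASH.components}
    best_key = dict(STRATUM)
    worst_key = dict(STRATUM, sex="female")
    set_stratum(frame, best_key, best)
    set_stratum(frame, worst_key, worst)
    cuts = ds.compute_cutpoints(frame, weights, DASH)
    totals = ds.score_strata(frame, DASH, cuts)
    assert totals.select(**best_key).draws[0, 0] == 40.0
    assert totals.select(**worst_key).draws[0, 0] == 8.0
    assert (totals.draws >= 8).all() and (totals.draws <= 40).all()


def test_med_extremes_score_8_and_0():
    frame, weights = population_frame(MED.factors, seed=6)
    best = {c.factor: (1e6 if c.direction == "healthy" else 0.0) for c in MED.components}
    worst = {c.factor: (0.0 if c.direction == "healthy" else 1e6) for c in MED.components}
    best_key = dict(STRATUM)
    worst_key = dict(STRATUM, sex="female")
    set_stratum(frame, best_key, best)
    set_stratum(frame, worst_key, worst)
    cuts = ds.compute_cutpoints(frame, weights, MED)
    totals = ds.score_strata(frame, MED, cuts)
    assert totals.select(**best_key).draws[0, 0] == 8.0
    assert totals.select(**worst_key).draws[0, 0] == 0.0
    assert (totals.draws >= 0).all() and (totals.draws <= 8).all()


def test_healthy_monotonicity():
    """Raising a healthy component's intake never lowers the total;
    raising an unhealthy component's never raises it."""
    frame, weights = population_frame(DASH.factors, seed=7)
    cuts = ds.compute_cutpoints(frame, weights, DASH)
    base = ds.score_strata(frame, DASH, cuts)
    for factor, direction in [("fruit", "healthy"), ("sodium", "unhealthy")]:
        bumped = DrawFrame(frame.index.copy(), frame.draws.copy())
        m = (bumped.index["factor"] == factor).to_numpy()
        bumped.draws[m] *= 1.5
        after = ds.score_strata(bumped, DASH, cuts)
        delta = after.draws - base.draws
        assert (delta >= 0).all() if direction == "healthy" else (delta <= 0).all()


def test_cutpoints_frozen_across_years():
    """Scoring 1990 uses byte-identical cutpoints computed from 2018."""
    frame18, weights = population_frame(MED.factors, seed=8)
    cuts = ds.compute_cutpoints(frame18, weights, MED)
    again = ds.compute_cutpoints(frame18, weights, MED)
    assert cuts.to_dict() == again.to_dict()
    frame90 = DrawFrame(frame18.index.assign(year=1990), frame18.draws * 1.3)
    t90 = ds.score_strata(frame90, MED, cuts)  # same CutpointSet object
    assert len(t90) == len(frame90.index[["country"]].drop_duplicates()) * 264


def test_missing_component_factor_skips_stratum(caplog):
    frame, weights = population_frame(MED.factors, seed=9)
    # drop one stratum's fish row entirely
    m = ~(
        (frame.index["factor"] == "fish")
        & (frame.index["sex"] == "male")
        & (frame.index["age_group"] == "30-34")
        & (frame.index["education"] == "<6y")
        & (frame.index["urbanicity"] == "urban")
        & (frame.index["country"] == "R1C1")
    ).to_numpy()
    frame2 = DrawFrame(frame.index[m], frame.draws[m])
    cuts = ds.compute_cutpoints(frame2, weights, MED)
    with caplog.at_level("WARNING"):
        totals = ds.score_strata(frame2, MED, cuts)
    assert len(totals) == 2 * 264 - 1
    assert "not scored" in caplog.text


def test_cutpoint_required_for_empirical_patterns():
    frame, _ = population_frame(DASH.factors, seed=10)
    with pytest.raises(ValueError, match="cutpoints"):
        ds.score_strata(frame, DASH)


def test_definition_loading_and_ranges():
    assert len(AHEI.components) == 9 and AHEI.score_range == (0.0, 100.0)
    assert len(DASH.components) == 8 and DASH.score_range == (8.0, 40.0)
    assert len(MED.components) == 8 and MED.score_range == (0.0, 8.0)
    assert AHEI.rescale == (100, 90)
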