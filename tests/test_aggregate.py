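"""Aggregation, contrasts, time changes and correlations versus
independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import dietscore as ds
from dietscore.draws import DrawFrame, summarize_draws
from dietscore.strata import STRATUM_COLUMNS, strata_frame


def random_scores(seed=0, n_draws=200, countries=("R1C1", "R1C2"), year=2018,
                  pattern="AHEI", lo=0.0, hi=100.0):
    rng = np.random.default_rng(seed)
    sf = strata_frame()
    frames, weights = [], []
    for country in countries:
        idx = sf.copy()
        idx.insert(0, "year", year)
        idx.insert(0, "country", country)
        idx["pattern"] = pattern
        frames.append(DrawFrame(idx, rng.uniform(lo, hi, size=(len(sf), n_draws))))
        wblock = sf.copy()
        wblock.insert(0, "year", year)
        wblock.insert(0, "country", country)
        wblock["persons"] = rng.uniform(10, 1e5, len(sf))
        weights.append(wblock)
    from dietscore.draws import concat_drawframes

    return concat_drawframes(frames), pd.concat(weights, ignore_index=True)


def test_weighted_mean_of_constants():
    idx = strata_frame().iloc[:2].copy()
    idx.insert(0, "year", 2018)
    idx.insert(0, "country", "R1C1")
    idx["pattern"] = "AHEI"
    scores = DrawFrame(idx, np.array([[40.0] * 10, [20.0] * 10]))
    w = idx[["country", "year"] + STRATUM_COLUMNS].copy()
    w["persons"] = [0.75, 0.25]
    (est,) = ds.aggregate(scores, w)
    assert est.median == pytest.approx(35.0)
    assert est.ui_low == est.ui_high == pytest.approx(35.0)  # UI width 0


def test_single_stratum_aggregate_is_identity():
    scores, weights = random_scores(seed=1)
    one = scores.select(
        country="R1C1", sex="male", age_group="30-34", education="<6y",
        urbanicity="urban",
    )
    (est,) = ds.aggregate(one, weights)
    med, lo, hi = summarize_draws(one.draws[0])
    assert (est.median, est.ui_low, est.ui_high) == (med, lo, hi)


def test_aggregate_matches_bruteforce_oracle_50_strata():
    rng = np.random.default_rng(2)
    scores, weights = random_scores(seed=2)
    pick = rng.choice(len(scores), size=50, replace=False)
    sub = DrawFrame(scores.index.iloc[pick], scores.draws[pick])
    (est,) = ds.aggregate(sub, weights)
    # brute force: loop draws, loop strata
    w = sub.index.merge(weights, on=["country", "year"] + STRATUM_COLUMNS)["persons"].to_numpy()
    oracle = np.array(
        [sum(wi * x for wi, x in zip(w, sub.draws[:, d])) / w.sum()
         for d in range(sub.n_draws)]
    )
    np.testing.assert_allclose(est.draws, oracle, atol=1e-12, rtol=0)
    assert est.median == pytest.approx(np.quantile(oracle, 0.5), abs=1e-12)


def test_aggregate_invariant_to_weight_rescaling():
    scores, weights = random_scores(seed=3)
    (a,) = ds.aggregate(scores, weights)
    weights2 = weights.assign(persons=weights.persons * 7.3)
    (b,) = ds.aggregate(scores, weights2)
    np.testing.assert_allclose(a.draws, b.draws, rtol=1e-12)


def test_global_equals_weighted_mean_of_regions():
    scores, weights = random_scores(seed=4, countries=("R1C1", "R1C2", "R2C1"))
    region_of = {"R1C1": "R1", "R1C2": "R1", "R2C1": "R2"}
    (glob,) = ds.aggregate(scores, weights)
    regional = ds.aggregate(scores, weights, scope="region", region_of=region_of)
    wsum = {
        r: weights[weights.country.map(region_of) == r]["persons"].sum()
        for r in ("R1", "R2")
    }
    combined = sum(wsum[e.scope] * e.draws for e in regional) / sum(wsum.values())
    np.testing.assert_allclose(glob.draws, combined, rtol=1e-12)


def test_zero_population_filter_is_an_error():
    scores, weights = random_scores(seed=5)
    weights.loc[weights.sex == "female", "persons"] = 0.0
    with pytest.raises(ValueError, match="zero population"):
        ds.aggregate(scores, weights, filter={"sex": "female"})
    with pytest.raises(ValueError, match="no strata"):
        ds.aggregate(scores, weights, filter={"sex": "unknown"})


# -- contrasts ----------------------------------------------------------
def test_constant_education_shift_gives_constant_difference():
    scores, weights = random_scores(seed=6)
    idx = scores.index
    draws = np.full_like(scores.draws, 30.0)
    draws[(idx.education == ">=12y").to_numpy()] = 33.0
    scores = DrawFrame(idx, draws)
    (est,) = ds.contrast_groups(scores, weights, "education")
    assert est.median == pytest.approx(3.0)
    assert est.ui_high - est.ui_low == pytest.approx(0.0, abs=1e-12)


def test_identical_groups_contrast_to_zero():
    scores, weights = random_scores(seed=7)
    idx = scores.index
    base = scores.draws.copy()
    urban = (idx.urbanicity == "urban").to_numpy()
    # mirror urban values onto rural partners
    key = ["country", "year", "sex", "age_group", "education"]
    a = idx[urban].reset_index()
    b = idx[~urban].reset_index()
    pairs = a.merge(b, on=key)
    base[pairs["index_y"].to_numpy()] = base[pairs["index_x"].to_numpy()]
    (est,) = ds.contrast_groups(DrawFrame(idx, base), weights, "urbanicity")
    assert est.median == pytest.approx(0.0, abs=1e-12)


def test_contrast_matches_pairwise_oracle_and_antisymmetry():
    scores, weights = random_scores(seed=8)
    (ab,) = ds.contrast_groups(scores, weights, "urbanicity", levels=("urban", "rural"))
    (ba,) = ds.contrast_groups(scores, weights, "urbanicity", levels=("rural", "urban"))
    np.testing.assert_allclose(ab.draws, -ba.draws, atol=1e-12)
    # brute force pairwise oracle
    idx = scores.index
    wtab = idx.merge(weights, on=["country", "year"] + STRATUM_COLUMNS)["persons"].to_numpy()
    key_cols = ["country", "year", "sex", "age_group", "education"]
    num = np.zeros(scores.n_draws)
    den = 0.0
    for i in np.flatnonzero((idx.urbanicity == "urban").to_numpy()):
        row = idx.iloc[i]
        m = np.ones(len(idx), dtype=bool)
        for c in key_cols:
            m &= (idx[c] == row[c]).to_numpy()
        m &= (idx.urbanicity == "rural").to_numpy()
        (j,) = np.flatnonzero(m)
        pw = wtab[i] + wtab[j]
        num += pw * (scores.draws[i] - scores.draws[j])
        den += pw
    np.testing.assert_allclose(ab.draws, num / den, atol=1e-12)


def test_education_contrast_excludes_middle_level():
    scores, weights = random_scores(seed=9)
    (est,) = ds.contrast_groups(scores, weights, "education")
    assert est.filter == "education: >=12y - <6y"
    # middle level must not affect the estimate
    idx = scores.index
    mid = (idx.education == "6-<12y").to_numpy()
    draws2 = scores.draws.copy()
    draws2[mid] += 1000.0
    (est2,) = ds.contrast_groups(DrawFrame(idx, draws2), weights, "education")
    np.testing.assert_allclose(est.draws, est2.draws)


# -- change over time ---------------------------------------------------
def make_two_years(seed=0):
    s90, w90 = random_scores(seed=seed, year=1990)
    s18, w18 = random_scores(seed=seed + 100, year=2018)
    return s90, s18, w18


def test_uniform_change_recovered_exactly():
    s90, _, w18 = make_two_years(10)
    s18 = DrawFrame(s90.index.assign(year=2018), s90.draws + 1.5)
    (est,) = ds.change_over_time(s90, s18, w18)
    assert est.median == pytest.approx(1.5)
    assert est.ui_high - est.ui_low == pytest.approx(0.0, abs=1e-12)


def test_no_change_gives_zero():
    s90, _, w18 = make_two_years(11)
    s18 = DrawFrame(s90.index.assign(year=2018), s90.draws.copy())
    (est,) = ds.change_over_time(s90, s18, w18)
    assert est.median == 0.0


def test_2018_standardization_removes_demographic_drift():
    """If stratum scores are identical in both years but population
    weights shift, the standardized change is 0 while a naive crude-mean
    difference (aggregate each year with its own weights) is not."""
    s90, _, w18 = make_two_years(12)
    s18 = DrawFrame(s90.index.assign(year=2018), s90.draws.copy())
    rng = np.random.default_rng(13)
    w90 = w18.assign(year=1990, persons=rng.uniform(10, 1e5, len(w18)))
    (est,) = ds.change_over_time(s90, s18, w18)
    assert est.median == pytest.approx(0.0, abs=1e-12)
    (a90,) = ds.aggregate(s90, w90)
    (a18,) = ds.aggregate(s18, w18)
    naive = np.quantile(a18.draws - a90.draws, 0.5)
    assert abs(naive) > 0.05  # the crude contrast shows spurious change


def test_missing_year_is_an_error():
    s90, s18, w18 = make_two_years(14)
    both = ds.draws.concat_drawframes if False else None
    with pytest.raises(ValueError, match="exactly one year"):
        from dietscore.draws import concat_drawframes

        ds.change_over_time(concat_drawframes([s90, s18]), s18, w18)


# -- correlations -------------------------------------------------------
def test_spearman_rank_invariance_and_sign():
    # odd draw count: the median is an exact order statistic, so a
    # monotone transform of the draws transforms the medians exactly
    a, _ = random_scores(seed=15, n_draws=201)
    monotone = DrawFrame(a.index.assign(pattern="B"), np.exp(a.draws / 25.0))
    negated = DrawFrame(a.index.assign(pattern="C"), -a.draws)
    mat = ds.score_correlations({"A": a, "B": monotone, "C": negated}, year=2018)
    assert mat.loc["A", "B"] == pytest.approx(1.0)
    assert mat.loc["A", "C"] == pytest.approx(-1.0)
    assert np.allclose(mat.values, mat.values.T)
    assert np.allclose(np.diag(mat.values), 1.0)


def test_spearman_matches_rank_then_pearson_oracle():
    a, _ = random_scores(seed=16)
    b = DrawFrame(a.index.assign(pattern="B"), np.random.default_rng(17).uniform(0, 100, a.draws.shape))
    mat = ds.score_correlations({"A": a, "B": b}, year=2018)
    ra = pd.Series(a.medians()).rank().to_numpy()
    rb = pd.Series(b.medians()).rank().to_numpy()
    oracle = np.corrcoef(ra, rb)[0, 1]
    assert mat.loc["A", "B"] == pytest.approx(oracle, abs=1e-12)


def test_correlation_needs_three_strata():
    a, _ = random_scores(seed=18)
    tiny = DrawFrame(a.index.iloc[:2], a.draws[:2])
    tiny_b = DrawFrame(tiny.index.assign(pattern="B"), tiny.draws)
    with pytest.raises(ValueError, match="at least 3"):
        ds.score_correlations({"A": tiny, "B": tiny_b}, year=2018)
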