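"""Intake model: conjugate limits, structure, shrinkage and prediction."""

import numpy as np
import pandas as pd
import pytest

import dietscore as ds
from dietscore.draws import summarize_draws
from dietscore.model import ModelSpec, natural_cubic_basis
from dietscore.strata import strata_frame


def test_spline_basis_is_linear_beyond_boundary_knots():
    knots = np.array([10.0, 30.0, 50.0, 70.0])
    x = np.array([80.0, 90.0, 100.0])
    B = natural_cubic_basis(x, knots)
    # beyond the last knot every column is affine in x: second differences 0
    second = np.diff(B, n=2, axis=0)
    np.testing.assert_allclose(second, 0.0, atol=1e-9)


def test_retained_draw_count_is_enforced():
    with pytest.raises(ValueError, match="4000"):
        ModelSpec(chains=4, draws_per_chain=999)


def single_stratum_records(n_surveys=8, mean=150.0, rel_sd=0.3, n=400, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_surveys):
        m = mean * np.exp(rng.normal(0, rel_sd / np.sqrt(n)))
        rows.append(
            dict(
                survey_id=f"s{i}", country="R1C1", year=2018, method="24hr_recall",
                representative=True, sex="male", age_group="30-34",
                education="<6y", urbanicity="urban", factor="fruit",
                observed_mean=m, observed_sd=m * rel_sd, n=n,
            )
        )
    return pd.DataFrame(rows)


def test_conjugate_limit_single_stratum():
    """With one stratum and flat structure the posterior mean matches the
    precision-weighted sample log-mean within Monte-Carlo error."""
    recs = single_stratum_records()
    model = ds.IntakeModel(recs, {"R1C1": "R1"})
    res = model.fit(seed=1)
    pred = res.predict_strata([("R1C1", 2018)], factors=["fruit"])
    sub = pred.select(sex="male", age_group="30-34", education="<6y", urbanicity="urban")
    post_log = np.log(sub.draws[0])
    v = (0.3**2 / 400)  # per-record log variance
    sample = np.log(recs.observed_mean) + v / 2
    se = np.sqrt(v / len(recs))
    assert abs(post_log.mean() - sample.mean()) < 2 * np.hypot(se, post_log.std())


def test_predict_emits_exactly_264_strata_per_country_year_factor(small_fit, small_world):
    pred = small_fit.predict_strata([("R1C1", 2018), ("R1C2", 1990)])
    counts = pred.index.groupby(["country", "year", "factor"]).size()
    assert (counts == 264).all()
    assert len(counts) == 2 * len(small_world.config.factors)
    assert pred.n_draws == 4000
    assert (pred.draws > 0).all()


def test_summary_percentiles_match_sort_oracle(small_fit):
    pred = small_fit.predict_strata([("R1C1", 2018)], factors=["fruit"])
    s = pred.summary()
    x = np.sort(pred.draws, axis=1)

    def oracle(q):
        h = q * (x.shape[1] - 1)
        lo = np.floor(h).astype(int)
        return x[np.arange(len(x)), lo] + (h - lo) * (
            x[np.arange(len(x)), np.minimum(lo + 1, x.shape[1] - 1)] - x[np.arange(len(x)), lo]
        )

    np.testing.assert_allclose(s["median"], oracle(0.5), rtol=1e-12)
    np.testing.assert_allclose(s["ui_low"], oracle(0.025), rtol=1e-12)
    np.testing.assert_allclose(s["ui_high"], oracle(0.975), rtol=1e-12)


def test_unseen_country_gets_region_level_predictive(small_fit, small_world):
    """Two countries never observed share the same predictive parameters:
    the region effect plus the country-scale dispersion."""
    small_fit.model.region_of.setdefault("R1C9", "R1")
    small_fit.model.region_of.setdefault("R1C8", "R1")
    loc9, scale9 = small_fit.predictive_params("fruit", "R1C9")
    loc8, scale8 = small_fit.predictive_params("fruit", "R1C8")
    np.testing.assert_array_equal(loc9, loc8)
    np.testing.assert_array_equal(scale9, scale8)
    assert (scale9 > 0).all()
    locA, scaleA = small_fit.predictive_params("fruit", "R1C1")
    assert (scaleA == 0).all()
    assert not np.array_equal(loc9, locA)


def test_monotone_data_influence(small_world):
    """Adding surveys at a stratum never increases its posterior variance
    (tested on nested datasets)."""
    designs = [ds.SurveyDesign(f"R1C1-2018-s{i}", "R1C1", 2018) for i in range(4)]
    recs = ds.simulate_surveys(small_world, designs, seed=3)
    few = recs[recs.survey_id.isin(["R1C1-2018-s0"])]
    spec = ModelSpec(warmup=300)
    res_few = ds.IntakeModel(few, small_world.region_of, spec=spec).fit(["fruit"], seed=4)
    res_all = ds.IntakeModel(recs, small_world.region_of, spec=spec).fit(["fruit"], seed=4)
    v_few = np.var(np.log(res_few.predict_strata([("R1C1", 2018)], ["fruit"]).draws), axis=1)
    v_all = np.var(np.log(res_all.predict_strata([("R1C1", 2018)], ["fruit"]).draws), axis=1)
    assert np.median(v_all) < np.median(v_few)
    assert (v_all < v_few * 1.5).mean() > 0.95  # no systematic inflation


def test_zero_record_factor_is_explicit_error(small_records, small_world):
    model = ds.IntakeModel(small_records, small_world.region_of)
    with pytest.raises(ValueError, match="no survey records"):
        model.fit(["nonexistent_factor"], seed=0)


def test_diagnostics_monitor_convergence(small_fit):
    d = small_fit.diagnostics()
    assert {"factor", "param", "rhat", "ess"} <= set(d.columns)
    assert (d.rhat > 0.9).all()
    # the shared fit on clean synthetic data should be well mixed
    assert d.rhat.max() < 1.1
    summ = small_fit.summary()
    assert {"post_mean", "post_sd"} <= set(summ.columns)


def test_method_bias_coefficient_exists(small_fit):
    eff = small_fit.method_effect("fruit", "FFQ")
    assert eff.shape == (4000,)
    with pytest.raises(KeyError):
        small_fit.method_effect("fruit", "doubly_labelled_water")


def test_fit_reproducible_given_seed(small_world):
    designs = [ds.SurveyDesign("s0", "R1C1", 2018)]
    recs = ds.simulate_surveys(small_world, designs, seed=5)
    spec = ModelSpec(warmup=100)
    r1 = ds.IntakeModel(recs, small_world.region_of, spec=spec).fit(["fruit"], seed=9)
    r2 = ds.IntakeModel(recs, small_world.region_of, spec=spec).fit(["fruit"], seed=9)
    np.testing.assert_array_equal(r1.loc_draws("fruit"), r2.loc_draws("fruit"))
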