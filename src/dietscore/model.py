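"""Hierarchical Bayesian estimation of stratum-level mean intakes.

The model operates on the log of each survey-stratum sample mean.  For a
record j observing factor f in country c (region r), year t, stratum s,
from survey k with assessment method m:

    log(mean_j) ~ Normal(mu_j, v_j * phi_j)

    mu_j = alpha + u_r + u_c + u_{c,t} + u_k
           + beta_female + beta_edu[s] + beta_urban
           + spline(age_s)                       (natural cubic, age midpoints)
           + gamma_year * (t - 2004)/10
           + gamma_cov * x_{c,t}                 (country-year covariate)
           + delta_method[j]                     (vs. 24 h recall baseline)

with nested random effects

    u_r ~ N(0, sigma_region^2)        region
    u_c ~ N(0, sigma_country^2)       country
    u_{c,t} ~ N(0, sigma_cy^2)        country-year (absorbs country-specific
                                      departures from the shared trend)
    u_k ~ N(0, sigma_method(m_k)^2)   survey (between-survey heterogeneity,
                                      scale estimated per assessment method)

v_j is the delta-method variance of the log sample mean, (SD^2/n)/mean^2,
and phi_j = 1 + overdispersion excess for surveys that are not nationally
representative or not fully stratified, phi_j = 1 otherwise.  Records
from collapsed strata enter through a design row that is the
person-weighted average of the constituent strata's rows.

Everything is linear-Gaussian given the scale parameters, so the sampler
draws all location parameters jointly from their exact conditional
multivariate normal each sweep (the Gram matrices depend on the data only
through the scalar overdispersion multiplier, so they are precomputed),
with adaptive random-walk Metropolis steps on the log scales.  Four
chains of 1,000 retained post-warmup draws give the 4,000 posterior draws
carried through the rest of the pipeline; predictions are made at the
reference method with survey effects set to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .draws import N_DRAWS, DrawFrame, concat_drawframes
from .strata import (
    AGE_BANDS,
    AGE_MIDPOINTS,
    COLLAPSED,
    STRATUM_COLUMNS,
    strata_frame,
)
from .world import YEAR_CENTER

logger = logging.getLogger(__name__)

BASELINE_METHOD = "24hr_recall"


def natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots).

    Returns ``len(knots) - 1`` columns: the linear term plus K-2
    curvature terms (truncated-power construction).
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    K = len(knots)
    if K < 3:
        raise ValueError("need at least 3 knots")

    def d(k):
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - knots[-1], 0, None) ** 3
        return num / (knots[-1] - knots[k])

    dK1 = d(K - 2)
    cols = [x] + [d(k) - dK1 for k in range(K - 2)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class ModelSpec:
    """Priors, structure and MCMC settings for the intake model."""

    chains: int = 4
    warmup: int = 500
    draws_per_chain: int = 1000
    knot_step: int = 3  # spline knots at every third age-band midpoint
    include_time: bool = True
    include_covariate: bool = True
    include_country_year: bool = True
    include_survey_effects: bool = True
    baseline_method: str = BASELINE_METHOD
    # prior SDs (log-intake scale)
    intercept_sd: float = 10.0
    effect_sd: float = 2.0
    spline_sd: float = 2.0
    method_sd: float = 1.0
    time_sd: float = 1.0  # per decade
    covariate_sd: float = 2.0
    region_scale: float = 1.0  # half-normal scales of the variance components
    country_scale: float = 1.0
    country_year_scale: float = 0.5
    survey_scale: float = 0.5
    overdisp_scale: float = 1.0  # half-normal scale for the variance excess
    pool_variances: bool = True  # pool relative variances within surveys
    delta_correction: bool = True  # second-order log-sample-mean correction
    min_obs_var: float = 1e-7
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.chains * self.draws_per_chain != N_DRAWS:
            raise ValueError(
                f"chains * draws_per_chain must equal {N_DRAWS}, got "
                f"{self.chains} * {self.draws_per_chain}"
            )

    @property
    def age_knots(self) -> np.ndarray:
        mids = np.array([AGE_MIDPOINTS[a] for a in AGE_BANDS])
        knots = mids[:: self.knot_step]
        if knots[-1] != mids[-1]:
            knots = np.append(knots, mids[-1])
        return knots


@dataclass
class _FactorDesign:
    """Prepared per-factor data: design matrix, variances, bookkeeping."""

    y: np.ndarray
    v: np.ndarray
    od: np.ndarray  # overdispersion flags
    X: np.ndarray  # full design incl. all random-effect dummies
    columns: list[str]
    p_fixed: int
    regions: list[str]
    countries: list[str]
    country_years: list[tuple[str, int]]
    surveys: list[str]
    survey_method: list[str]  # method of each survey, aligned with surveys
    prior_sd_fixed: np.ndarray


def _spline_block(spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Centered, orthonormalized spline basis at the 22 age midpoints.

    The raw truncated-power basis is extremely collinear; representing a
    modest curve then needs large opposing coefficients, which any
    reasonable prior would distort.  A QR orthonormalization over the
    evaluation points spans the same function space with coefficients on
    the scale of the curve itself.
    """
    mids = np.array([AGE_MIDPOINTS[a] for a in AGE_BANDS])
    B = natural_cubic_basis(mids, spec.age_knots)
    B = B - B.mean(axis=0)
    Q, _ = np.linalg.qr(B)
    B = Q * np.sqrt(len(mids))  # unit-SD columns
    names = [f"age_s{i + 1}" for i in range(B.shape[1])]
    return B, names


def _stratum_design(spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Stratum-level design block for the 264 canonical strata."""
    sf = strata_frame()
    B, snames = _spline_block(spec)
    age_ix = {a: i for i, a in enumerate(AGE_BANDS)}
    rows = B[sf["age_group"].map(age_ix).to_numpy()]
    cols = [
        (sf["sex"] == "female").to_numpy(float),
        (sf["education"] == "6-<12y").to_numpy(float),
        (sf["education"] == ">=12y").to_numpy(float),
        (sf["urbanicity"] == "urban").to_numpy(float),
    ]
    names = ["female", "edu_mid", "edu_high", "urban"]
    return np.column_stack(cols + [rows]), names + snames


class IntakeModel:
    """Model object: survey records plus structure; ``fit`` runs MCMC.

    Parameters
    ----------
    records : DataFrame
        Survey records in the :data:`dietscore.surveys.SURVEY_COLUMNS`
        layout.  Collapsed dimensions carry the sentinel ``"all"``.
    region_of : mapping
        country -> region membership (required for the nested effects).
    covariates : DataFrame, optional
        Long table (factor, country, year, value) of country-year
        covariates; used when the spec includes a covariate slope.
    weights : DataFrame, optional
        Population weights, used to form the person-weighted design rows
        of collapsed records (equal weights are used if omitted).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        region_of: dict[str, str],
        covariates: pd.DataFrame | None = None,
        weights: pd.DataFrame | None = None,
        spec: ModelSpec | None = None,
    ) -> None:
        self.records = records.reset_index(drop=True)
        self.region_of = dict(region_of)
        self.covariates = covariates
        self.weights = weights
        self.spec = spec or ModelSpec()
        missing = set(self.records["country"]) - set(self.region_of)
        if missing:
            raise ValueError(f"region membership unknown for countries {sorted(missing)}")
        if (self.records["observed_mean"] <= 0).any():
            raise ValueError("observed means must be strictly positive")

    # ------------------------------------------------------------------
    def _covariate_value(self, factor: str, country: str, year: int) -> float:
        if self.covariates is None:
            return 0.0
        tab = self.covariates
        hit = tab[
            (tab["factor"] == factor)
            & (tab["country"] == country)
            & (tab["year"] == year)
        ]
        if len(hit) == 0:
            logger.warning(
                "no covariate for factor=%s country=%s year=%s; using 0",
                factor, country, year,
            )
            return 0.0
        return float(hit["value"].iloc[0])

    def _persons_for(self, country: str, year: int) -> np.ndarray:
        sf = strata_frame()
        if self.weights is None:
            return np.ones(len(sf))
        w = self.weights
        blk = w[(w["country"] == country) & (w["year"] == year)]
        if len(blk) == 0:
            return np.ones(len(sf))
        merged = sf.merge(blk, on=STRATUM_COLUMNS, how="left")
        return merged["persons"].fillna(0.0).to_numpy()

    def _build_design(self, factor: str) -> _FactorDesign:
        spec = self.spec
        recs = self.records[self.records["factor"] == factor].reset_index(drop=True)
        if len(recs) == 0:
            raise ValueError(f"no survey records for factor {factor!r}")
        S, snames = _stratum_design(spec)
        sf = strata_frame()
        stratum_ix = {tuple(r): i for i, r in enumerate(sf.to_numpy())}

        countries = sorted(set(self.region_of))
        regions = sorted(set(self.region_of.values()))

        methods = [m for m in pd.unique(recs["method"]) if m != spec.baseline_method]
        n = len(recs)
        n_s = S.shape[1]

        stratum_rows = np.empty((n, n_s))
        collapsed_mask = (
            recs[STRATUM_COLUMNS].apply(lambda c: c.eq(COLLAPSED)).any(axis=1)
        ).to_numpy()
        full = ~collapsed_mask
        if full.any():
            keys = list(map(tuple, recs.loc[full, STRATUM_COLUMNS].to_numpy()))
            stratum_rows[full] = S[[stratum_ix[k] for k in keys]]
        if collapsed_mask.any():
            persons_cache: dict[tuple, np.ndarray] = {}
            for i in np.flatnonzero(collapsed_mask):
                row = recs.iloc[i]
                key = (row["country"], row["year"])
                if key not in persons_cache:
                    persons_cache[key] = self._persons_for(*key)
                persons = persons_cache[key]
                sel = np.ones(len(sf), dtype=bool)
                for dim in STRATUM_COLUMNS:
                    if row[dim] != COLLAPSED:
                        sel &= (sf[dim] == row[dim]).to_numpy()
                w = persons[sel]
                w = w / w.sum() if w.sum() > 0 else np.full(sel.sum(), 1 / sel.sum())
                stratum_rows[i] = w @ S[sel]

        cols = [np.ones(n)]
        names = ["intercept"]
        prior = [spec.intercept_sd]
        cols.append(stratum_rows)
        names += snames
        prior += [spec.effect_sd] * 4 + [spec.spline_sd] * (n_s - 4)
        if spec.include_time:
            cols.append(((recs["year"] - YEAR_CENTER) / 10.0).to_numpy()[:, None])
            names.append("year_decade")
            prior.append(spec.time_sd)
        if spec.include_covariate and self.covariates is not None:
            tab = self.covariates
            ftab = tab[tab["factor"] == factor].set_index(["country", "year"])["value"]
            key = pd.MultiIndex.from_frame(recs[["country", "year"]])
            cov = ftab.reindex(key).to_numpy()
            n_miss = int(np.isnan(cov).sum())
            if n_miss:
                logger.warning("%d records missing covariate for %s; using 0", n_miss, factor)
                cov = np.nan_to_num(cov)
            cols.append(cov[:, None])
            names.append("covariate")
            prior.append(spec.covariate_sd)
        for m in methods:
            cols.append((recs["method"] == m).to_numpy(float)[:, None])
            names.append(f"method_{m}")
            prior.append(spec.method_sd)
        Xfix = np.column_stack(cols)
        p_fixed = Xfix.shape[1]

        blocks = [Xfix]

        def dummies(labels: Sequence, keys: pd.Series) -> np.ndarray:
            ix = {k: i for i, k in enumerate(labels)}
            Z = np.zeros((n, len(labels)))
            Z[np.arange(n), keys.map(ix).to_numpy()] = 1.0
            return Z

        rec_region = recs["country"].map(self.region_of)
        blocks.append(dummies(regions, rec_region))
        blocks.append(dummies(countries, recs["country"]))
        names += [f"region_{r}" for r in regions] + [f"country_{c}" for c in countries]

        country_years: list[tuple[str, int]] = []
        if spec.include_country_year:
            cy = list(map(tuple, recs[["country", "year"]].drop_duplicates().to_numpy()))
            country_years = sorted(cy)
            keys = pd.Series(list(zip(recs["country"], recs["year"])))
            blocks.append(dummies(country_years, keys))
            names += [f"cy_{c}_{t}" for c, t in country_years]

        surveys: list[str] = []
        survey_method: list[str] = []
        if spec.include_survey_effects:
            surveys = sorted(recs["survey_id"].unique())
            meth = recs.drop_duplicates("survey_id").set_index("survey_id")["method"]
            survey_method = [meth[s] for s in surveys]
            blocks.append(dummies(surveys, recs["survey_id"]))
            names += [f"survey_{s}" for s in surveys]

        mean = recs["observed_mean"].to_numpy(float)
        sd = recs["observed_sd"].to_numpy(float)
        nn = recs["n"].to_numpy(float)
        rel_var = sd**2 / mean**2
        if spec.pool_variances:
            # per-record variance estimates are noisy and correlated with
            # the observed mean (log-normal data), which biases 1/v
            # weighting; pooling the relative variance within each survey
            # removes both problems at negligible cost in flexibility
            pooled = (
                pd.Series(rel_var).groupby(recs["survey_id"]).transform("mean").to_numpy()
            )
            rel_var = pooled
        v = np.maximum(rel_var / nn, spec.min_obs_var)
        y = np.log(mean)
        if spec.delta_correction:
            # E[log(sample mean)] = log(true mean) - v/2 to second order
            y = y + v / 2.0
        od = (~recs["representative"].astype(bool).to_numpy()) | collapsed_mask

        return _FactorDesign(
            y=y, v=v, od=od,
            X=np.column_stack(blocks),
            columns=names,
            p_fixed=p_fixed,
            regions=regions,
            countries=countries,
            country_years=country_years,
            surveys=surveys,
            survey_method=survey_method,
            prior_sd_fixed=np.array(prior),
        )

    # ------------------------------------------------------------------
    def fit(self, factors: list[str] | None = None, seed: int = 0) -> "IntakeResults":
        """Run MCMC for each factor and return the fitted results."""
        if factors is None:
            factors = list(pd.unique(self.records["factor"]))
        root = np.random.SeedSequence(seed)
        states: dict[str, dict] = {}
        for fss, factor in zip(root.spawn(len(factors)), factors):
            design = self._build_design(factor)
            states[factor] = _run_mcmc(design, self.spec, fss)
            states[factor]["design"] = design
            logger.info("fitted factor %s (%d records)", factor, len(design.y))
        return IntakeResults(self, states, seed)


def _halfnormal_logpdf_on_log(log_x: float, scale: float) -> float:
    """log density of HalfNormal(scale) at x=exp(log_x), plus the
    log-Jacobian of the log transform."""
    x = np.exp(log_x)
    return -(x**2) / (2 * scale**2) + log_x


class _ScaleSampler:
    """Adaptive random-walk Metropolis on the log of a scale parameter."""

    def __init__(self, init: float, prior_scale: float, warmup: int) -> None:
        self.log_s = np.log(init)
        self.prior_scale = prior_scale
        self.step = 0.5
        self.warmup = warmup

    @property
    def value(self) -> float:
        return float(np.exp(self.log_s))

    def update_gaussian(self, u: np.ndarray, it: int, rng) -> float:
        """Posterior step given u ~ N(0, s^2) i.i.d."""
        uu = float(u @ u)
        k = len(u)

        def lp(ls):
            return (
                -k * ls
                - uu / (2 * np.exp(2 * ls))
                + _halfnormal_logpdf_on_log(ls, self.prior_scale)
            )

        return self._step(lp, it, rng)

    def _step(self, lp, it: int, rng) -> float:
        prop = self.log_s + self.step * rng.standard_normal()
        acc = 0.0
        if np.log(rng.uniform()) < lp(prop) - lp(self.log_s):
            self.log_s, acc = prop, 1.0
        if it < self.warmup:
            self.step *= np.exp(0.05 * (acc - 0.44))
        return self.value


def _run_mcmc(design: _FactorDesign, spec: ModelSpec, ss: np.random.SeedSequence) -> dict:
    y, v, od, X = design.y, design.v, design.od, design.X
    q = X.shape[1]
    p = design.p_fixed
    R, C = len(design.regions), len(design.countries)
    n_cy = len(design.country_years)
    n_sv = len(design.surveys)
    w0 = 1.0 / v
    Xn, Xo = X[~od], X[od]
    wn, wo = w0[~od], w0[od]
    B0 = (Xn * wn[:, None]).T @ Xn
    c0 = Xn.T @ (wn * y[~od])
    Bod = (Xo * wo[:, None]).T @ Xo
    cod = Xo.T @ (wo * y[od])
    n_od = int(od.sum())

    prior_fixed_prec = 1.0 / design.prior_sd_fixed**2
    methods_present = sorted(set(design.survey_method))
    sv_method_ix = {
        m: np.array([i for i, sm in enumerate(design.survey_method) if sm == m])
        for m in methods_present
    }

    sl_r = slice(p, p + R)
    sl_c = slice(p + R, p + R + C)
    sl_cy = slice(p + R + C, p + R + C + n_cy)
    sl_sv = slice(p + R + C + n_cy, q)

    # per-row group index within each random-effect block (argmax of the
    # one-hot dummies), used by the interweaving scale updates
    def _row_groups(sl: slice) -> np.ndarray:
        return np.argmax(X[:, sl], axis=1)

    gr_r, gr_c = _row_groups(sl_r), _row_groups(sl_c)
    gr_cy = _row_groups(sl_cy) if n_cy else None
    gr_sv = _row_groups(sl_sv) if n_sv else None
    sv_of_row = gr_sv
    method_rows = (
        {
            m: np.flatnonzero(np.isin(sv_of_row, ix))
            for m, ix in sv_method_ix.items()
        }
        if n_sv
        else {}
    )

    n_keep = spec.draws_per_chain
    total = spec.warmup + n_keep
    loc_draws = np.empty((spec.chains, n_keep, q), dtype=np.float32)
    # sigma_region, sigma_country, sigma_cy, delta, then one sigma per method
    n_scales = 4 + len(methods_present)
    scale_draws = np.empty((spec.chains, n_keep, n_scales))

    for chain, css in enumerate(ss.spawn(spec.chains)):
        rng = np.random.default_rng(css)
        s_r = _ScaleSampler(0.3, spec.region_scale, spec.warmup)
        s_c = _ScaleSampler(0.3, spec.country_scale, spec.warmup)
        s_cy = _ScaleSampler(0.1, spec.country_year_scale, spec.warmup)
        s_od = _ScaleSampler(0.1, spec.overdisp_scale, spec.warmup)
        s_m = {m: _ScaleSampler(0.1, spec.survey_scale, spec.warmup) for m in methods_present}
        loc = np.zeros(q)
        for it in range(total):
            phi = 1.0 + s_od.value
            prior_prec = np.empty(q)
            prior_prec[:p] = prior_fixed_prec
            prior_prec[sl_r] = 1 / s_r.value**2
            prior_prec[sl_c] = 1 / s_c.value**2
            if n_cy:
                prior_prec[sl_cy] = 1 / s_cy.value**2
            if n_sv:
                sv_prec = np.empty(n_sv)
                for m, ix in sv_method_ix.items():
                    sv_prec[ix] = 1 / s_m[m].value**2
                prior_prec[sl_sv] = sv_prec
            A = B0 + Bod / phi
            A[np.diag_indices(q)] += prior_prec
            b = c0 + cod / phi
            L = cholesky(A, lower=True)
            mean = cho_solve((L, True), b)
            loc = mean + solve_triangular(L.T, rng.standard_normal(q), lower=False)

            s_r.update_gaussian(loc[sl_r], it, rng)
            s_c.update_gaussian(loc[sl_c], it, rng)
            if n_cy:
                s_cy.update_gaussian(loc[sl_cy], it, rng)
            if n_sv:
                u_sv = loc[sl_sv]
                for m, ix in sv_method_ix.items():
                    s_m[m].update_gaussian(u_sv[ix], it, rng)

            resid = y - X @ loc
            if n_od:
                S_od = float((resid[od] ** 2 * wo).sum())

                def lp_d(ld):
                    d = np.exp(ld)
                    return (
                        -n_od / 2 * np.log1p(d)
                        - S_od / (2 * (1 + d))
                        + _halfnormal_logpdf_on_log(ld, spec.overdisp_scale)
                    )

                s_od._step(lp_d, it, rng)

            # interweaving (ancillarity-sufficiency) rescale of each
            # variance component: holding u_tilde = u / s fixed, s is a
            # plain regression coefficient with a Gaussian conditional;
            # this breaks the funnel that pins centered Gibbs when a
            # scale approaches zero.  The half-normal prior symmetrizes
            # to N(0, scale^2) and a negative draw flips into u.
            w_phi = w0.copy()
            if n_od:
                w_phi[od] /= 1.0 + s_od.value

            def interweave(sl, grp, rows, sampler, idx=None):
                s = sampler.value
                if s < 1e-12:
                    return
                u = loc[sl].copy()
                if idx is not None:
                    u_sub = u[idx]
                else:
                    u_sub = u
                ut = u_sub / s
                grp_r = grp if rows is None else grp[rows]
                if idx is not None:
                    # map block-local survey index to position within idx
                    remap = np.full(len(u), -1)
                    remap[idx] = np.arange(len(idx))
                    a = ut[remap[grp_r]]
                else:
                    a = ut[grp_r]
                r_rows = slice(None) if rows is None else rows
                r = resid[r_rows] + (u[grp_r] if idx is None else u[grp_r])
                ww = w_phi[r_rows]
                prec = float((a * a * ww).sum()) + 1.0 / sampler.prior_scale**2
                mean = float((a * r * ww).sum()) / prec
                s_new = mean + rng.standard_normal() / np.sqrt(prec)
                if idx is not None:
                    u_new = u.copy()
                    u_new[idx] = s_new * ut
                else:
                    u_new = s_new * ut
                resid[r_rows] = r - u_new[grp_r]
                loc[sl] = u_new
                sampler.log_s = float(np.log(max(abs(s_new), 1e-10)))

            interweave(sl_r, gr_r, None, s_r)
            interweave(sl_c, gr_c, None, s_c)
            if n_cy:
                interweave(sl_cy, gr_cy, None, s_cy)
            if n_sv:
                for m, ix in sv_method_ix.items():
                    interweave(sl_sv, gr_sv, method_rows[m], s_m[m], idx=ix)

            if it >= spec.warmup:
                k = it - spec.warmup
                loc_draws[chain, k] = loc
                scale_draws[chain, k, :4] = (s_r.value, s_c.value, s_cy.value, s_od.value)
                scale_draws[chain, k, 4:] = [s_m[m].value for m in methods_present]

    return {
        "loc": loc_draws,
        "scales": scale_draws,
        "scale_names": ["sigma_region", "sigma_country", "sigma_cy", "overdisp_excess"]
        + [f"sigma_survey_{m}" for m in methods_present],
        "columns": design.columns,
    }


class IntakeResults:
    """Fitted posterior state: draws, diagnostics and prediction."""

    def __init__(self, model: IntakeModel, states: dict[str, dict], seed: int) -> None:
        self.model = model
        self.spec = model.spec
        self._states = states
        self.seed = seed
        self._diagnostics: pd.DataFrame | None = None

    @property
    def factors(self) -> list[str]:
        return list(self._states)

    def loc_draws(self, factor: str) -> np.ndarray:
        """Flattened (4000, q) location-parameter draws."""
        st = self._states[factor]
        ch, d, q = st["loc"].shape
        return st["loc"].reshape(ch * d, q).astype(float)

    def columns(self, factor: str) -> list[str]:
        return self._states[factor]["columns"]

    def coef_draws(self, factor: str, name: str) -> np.ndarray:
        cols = self.columns(factor)
        if name not in cols:
            raise KeyError(f"no coefficient {name!r} for factor {factor!r}")
        return self.loc_draws(factor)[:, cols.index(name)]

    def scale_draws(self, factor: str, name: str) -> np.ndarray:
        st = self._states[factor]
        names = st["scale_names"]
        if name not in names:
            raise KeyError(f"no scale parameter {name!r}; have {names}")
        return st["scales"].reshape(-1, len(names))[:, names.index(name)]

    def method_effect(self, factor: str, method: str) -> np.ndarray:
        """Posterior draws of a method's log-scale bias coefficient."""
        return self.coef_draws(factor, f"method_{method}")

    # -- diagnostics ----------------------------------------------------
    def diagnostics(self) -> pd.DataFrame:
        """Split-Rhat and effective sample size per monitored parameter."""
        if self._diagnostics is not None:
            return self._diagnostics
        import arviz as az

        rows = []
        for factor, st in self._states.items():
            design = st["design"]
            p = design.p_fixed
            post = {
                name: st["loc"][:, :, i].astype(float)
                for i, name in enumerate(st["columns"][:p])
            }
            for i, name in enumerate(st["scale_names"]):
                post[name] = st["scales"][:, :, i]
            idata = az.from_dict(posterior=post)
            rhat = az.rhat(idata)
            ess = az.ess(idata)
            for name in post:
                rows.append(
                    (factor, name, float(rhat[name].values), float(ess[name].values))
                )
        self._diagnostics = pd.DataFrame(rows, columns=["factor", "param", "rhat", "ess"])
        bad = self._diagnostics[self._diagnostics["rhat"] > self.spec.rhat_threshold]
        if len(bad):
            logger.warning(
                "possible non-convergence (Rhat > %.2f) for %d parameters:\n%s",
                self.spec.rhat_threshold, len(bad), bad.to_string(index=False),
            )
        return self._diagnostics

    @property
    def converged(self) -> bool:
        d = self.diagnostics()
        return bool((d["rhat"] <= self.spec.rhat_threshold).all())

    def summary(self) -> pd.DataFrame:
        """Posterior mean/SD and Rhat for every fixed effect, per factor."""
        diag = self.diagnostics().set_index(["factor", "param"])
        rows = []
        for factor in self.factors:
            draws = self.loc_draws(factor)
            design = self._states[factor]["design"]
            for i, name in enumerate(self.columns(factor)[: design.p_fixed]):
                rhat = (
                    diag.loc[(factor, name), "rhat"]
                    if (factor, name) in diag.index
                    else np.nan
                )
                rows.append((factor, name, draws[:, i].mean(), draws[:, i].std(), rhat))
        return pd.DataFrame(
            rows, columns=["factor", "param", "post_mean", "post_sd", "rhat"]
        )

    # -- prediction -----------------------------------------------------
    def _fixed_row_base(self, factor: str, country: str, year: int) -> np.ndarray:
        """Record-level part of the prediction row (at baseline method)."""
        cols = self.columns(factor)
        design = self._states[factor]["design"]
        row = np.zeros(design.p_fixed)
        row[cols.index("intercept")] = 1.0
        if "year_decade" in cols:
            row[cols.index("year_decade")] = (year - YEAR_CENTER) / 10.0
        if "covariate" in cols:
            row[cols.index("covariate")] = self.model._covariate_value(
                factor, country, year
            )
        return row

    def predictive_params(self, factor: str, country: str) -> tuple[np.ndarray, np.ndarray]:
        """Country-level predictive location and scale draws.

        For a fitted country the location is region + country effect and
        the scale is zero; for an unseen country the location is the
        region effect alone and the scale is the posterior country-level
        SD — the region-level predictive distribution, identical for
        every unseen country of that region.
        """
        st = self._states[factor]
        design = st["design"]
        loc = self.loc_draws(factor)
        p, R = design.p_fixed, len(design.regions)
        region = self.model.region_of[country]
        u_r = loc[:, p + design.regions.index(region)]
        if country in design.countries:
            return u_r + loc[:, p + R + design.countries.index(country)], np.zeros(loc.shape[0])
        return u_r, self.scale_draws(factor, "sigma_country")

    def predict_strata(
        self,
        targets: list[tuple[str, int]],
        factors: list[str] | None = None,
    ) -> DrawFrame:
        """Posterior intake draws for all 264 strata of each target.

        Returns a :class:`DrawFrame` with one row per
        country-year-stratum-factor and 4,000 natural-scale draws.
        Predictions are at the reference assessment method with survey
        effects at zero and no overdispersion.  A country never observed
        by the model receives the region-level predictive distribution; a
        country-year without data receives a fresh country-year effect
        from its posterior scale.
        """
        factors = factors or self.factors
        sf = strata_frame()
        S, _ = _stratum_design(self.spec)
        frames = []
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 2**16 + 1]))
        for factor in factors:
            st = self._states[factor]
            design = st["design"]
            loc = self.loc_draws(factor)
            p = design.p_fixed
            R, C = len(design.regions), len(design.countries)
            cy_ix = {cy: i for i, cy in enumerate(design.country_years)}
            for country, year in targets:
                base = self._fixed_row_base(factor, country, year)
                u_country, u_scale = self.predictive_params(factor, country)
                if country not in design.countries:
                    logger.warning(
                        "country %s not in fit for %s; using region-level "
                        "predictive distribution", country, factor,
                    )
                    u_country = u_country + rng.standard_normal(loc.shape[0]) * u_scale
                level = u_country
                if design.country_years:
                    key = (country, year)
                    if key in cy_ix:
                        level = level + loc[:, p + R + C + cy_ix[key]]
                    else:
                        s_cy = self.scale_draws(factor, "sigma_cy")
                        level = level + rng.standard_normal(loc.shape[0]) * s_cy
                fixed_part = np.tile(base, (len(sf), 1))
                fixed_part[:, 1 : 1 + S.shape[1]] = S
                log_mu = fixed_part @ loc[:, :p].T + level
                idx = sf.copy()
                idx.insert(0, "year", year)
                idx.insert(0, "country", country)
                idx["factor"] = factor
                frames.append(DrawFrame(idx, np.exp(log_mu)))
        out = concat_drawframes(frames)
        out.meta.update(seed=self.seed, standardized=False)
        return out.require_n_draws()
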