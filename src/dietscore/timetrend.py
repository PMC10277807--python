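"""Second-stage varying-slopes time model.

First-stage stratum estimates carry a single shared time trend; this
stage strengthens country-specific trends by fitting, per dietary factor,
a hierarchical linear model to the national log-mean series:

    y_ct ~ Normal(a_c + b_c * (t - tbar) [+ gamma * x_ct],  se_ct^2 + tau^2)
    (a_c, b_c) ~ MVN(mu, Sigma)

with the cross-country intercept-slope correlation rho = corr(Sigma)
estimated from the data.  Country lines are partially pooled toward the
cross-country distribution, and the adjusted country-year level replaces
the first-stage level draw-wise, preserving within-country-year stratum
structure and the 4,000-draw contract.

The sampler is a blocked Gibbs scheme: country lines and the population
mean are conjugate Gaussian updates, Sigma is a conjugate inverse-Wishart
update, and the residual scale tau moves by adaptive random-walk
Metropolis on the log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .draws import N_DRAWS, DrawFrame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimeTrendSpec:
    chains: int = 4
    warmup: int = 500
    draws_per_chain: int = 1000
    mu_sd: tuple[float, float] = (10.0, 1.0)  # prior SD of (intercept, slope) mean
    nu0: float = 4.0  # inverse-Wishart dof
    psi_diag: tuple[float, float] = (0.1**2, 0.01**2)  # inverse-Wishart scale
    tau_scale: float = 0.1  # half-normal scale of extra residual SD
    covariate_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.chains * self.draws_per_chain != N_DRAWS:
            raise ValueError(f"chains * draws_per_chain must equal {N_DRAWS}")


def national_log_series(intakes: DrawFrame, factor: str) -> pd.DataFrame:
    """Country-year national log-mean series from stratum-level draws.

    value = posterior mean (over draws) of the per-draw mean (over
    strata) of log intake; se = posterior SD of that per-draw mean.
    """
    sub = intakes.select(factor=factor)
    rows = []
    for (country, year), grp in sub.index.groupby(["country", "year"]).groups.items():
        logs = np.log(sub.draws[list(grp)])
        per_draw = logs.mean(axis=0)
        rows.append((country, int(year), per_draw.mean(), per_draw.std(ddof=1)))
    return pd.DataFrame(rows, columns=["country", "year", "value", "se"])


class TimeTrendModel:
    """Varying-slopes model over a country-year series.

    ``table`` needs columns country, year, value and optionally se and
    covariate.  Construct directly for a bare series, or via
    :func:`fit_time_model` to adjust first-stage intake draws.
    """

    def __init__(self, table: pd.DataFrame, spec: TimeTrendSpec | None = None) -> None:
        self.table = table.reset_index(drop=True)
        self.spec = spec or TimeTrendSpec()
        if not {"country", "year", "value"} <= set(self.table.columns):
            raise ValueError("table needs country, year, value columns")
        self.year_center = float(self.table["year"].mean())
        self.countries = sorted(self.table["country"].unique())
        if len(self.countries) < 2:
            raise ValueError("need at least two countries to pool across")

    def fit(self, seed: int = 0) -> "TimeTrendResults":
        spec = self.spec
        tab = self.table
        se = tab["se"].to_numpy(float) if "se" in tab else np.zeros(len(tab))
        has_cov = "covariate" in tab.columns
        xcov = tab["covariate"].to_numpy(float) if has_cov else None
        C = len(self.countries)
        c_ix = {c: i for i, c in enumerate(self.countries)}
        g = tab["country"].map(c_ix).to_numpy()
        t = (tab["year"].to_numpy(float) - self.year_center)
        y0 = tab["value"].to_numpy(float)
        X = np.column_stack([np.ones(len(tab)), t])

        n_keep = spec.draws_per_chain
        total = spec.warmup + n_keep
        ab_draws = np.empty((spec.chains, n_keep, C, 2))
        mu_draws = np.empty((spec.chains, n_keep, 2))
        rho_draws = np.empty((spec.chains, n_keep))
        tau_draws = np.empty((spec.chains, n_keep))
        gam_draws = np.empty((spec.chains, n_keep))

        psi0 = np.diag(spec.psi_diag) * spec.nu0
        mu_prior_prec = np.diag(1.0 / np.asarray(spec.mu_sd) ** 2)

        root = np.random.SeedSequence(seed)
        for chain, css in enumerate(root.spawn(spec.chains)):
            rng = np.random.default_rng(css)
            mu = np.zeros(2)
            Sigma = np.diag(spec.psi_diag)
            ab = np.zeros((C, 2))
            log_tau = np.log(0.05)
            gamma = 0.0
            step = 0.5
            for it in range(total):
                tau2 = np.exp(2 * log_tau)
                w = 1.0 / (se**2 + tau2)
                y = y0 - gamma * xcov if has_cov else y0
                Sinv = np.linalg.inv(Sigma)
                for c in range(C):
                    m = g == c
                    Xc, yc, wc = X[m], y[m], w[m]
                    prec = (Xc * wc[:, None]).T @ Xc + Sinv
                    rhs = Xc.T @ (wc * yc) + Sinv @ mu
                    Lc = np.linalg.cholesky(prec)
                    mean = np.linalg.solve(prec, rhs)
                    ab[c] = mean + np.linalg.solve(Lc.T, rng.standard_normal(2))
                # population mean
                prec_mu = C * Sinv + mu_prior_prec
                mean_mu = np.linalg.solve(prec_mu, Sinv @ ab.sum(axis=0))
                Lmu = np.linalg.cholesky(prec_mu)
                mu = mean_mu + np.linalg.solve(Lmu.T, rng.standard_normal(2))
                # covariance of country lines
                dev = ab - mu
                Sigma = invwishart.rvs(
                    df=spec.nu0 + C, scale=psi0 + dev.T @ dev, random_state=rng
                )
                # optional global covariate slope
                if has_cov:
                    fit_resid = y0 - (ab[g] * X).sum(axis=1)
                    prec_g = (xcov**2 * w).sum() + 1.0 / spec.covariate_sd**2
                    mean_g = (xcov * w * fit_resid).sum() / prec_g
                    gamma = mean_g + rng.standard_normal() / np.sqrt(prec_g)
                # residual scale tau (Metropolis on log tau)
                resid = y - (ab[g] * X).sum(axis=1)

                def lp(lt):
                    t2 = np.exp(2 * lt)
                    var = se**2 + t2
                    return (
                        -0.5 * (np.log(var).sum() + (resid**2 / var).sum())
                        - t2 / (2 * spec.tau_scale**2)
                        + lt
                    )

                prop = log_tau + step * rng.standard_normal()
                if np.log(rng.uniform()) < lp(prop) - lp(log_tau):
                    log_tau, acc = prop, 1.0
                else:
                    acc = 0.0
                if it < spec.warmup:
                    step *= np.exp(0.05 * (acc - 0.44))

                if it >= spec.warmup:
                    k = it - spec.warmup
                    ab_draws[chain, k] = ab
                    mu_draws[chain, k] = mu
                    rho_draws[chain, k] = Sigma[0, 1] / np.sqrt(Sigma[0, 0] * Sigma[1, 1])
                    tau_draws[chain, k] = np.exp(log_tau)
                    gam_draws[chain, k] = gamma

        return TimeTrendResults(
            model=self,
            ab=ab_draws.reshape(-1, C, 2),
            mu=mu_draws.reshape(-1, 2),
            rho=rho_draws.reshape(-1),
            tau=tau_draws.reshape(-1),
            gamma=gam_draws.reshape(-1),
            seed=seed,
        )


@dataclass
class TimeTrendResults:
    """Posterior draws of the varying-slopes model."""

    model: TimeTrendModel
    ab: np.ndarray  # (4000, C, 2)
    mu: np.ndarray  # (4000, 2)
    rho: np.ndarray  # (4000,)
    tau: np.ndarray
    gamma: np.ndarray
    seed: int

    @property
    def countries(self) -> list[str]:
        return self.model.countries

    def intercept_draws(self, country: str) -> np.ndarray:
        return self.ab[:, self.countries.index(country), 0]

    def slope_draws(self, country: str) -> np.ndarray:
        return self.ab[:, self.countries.index(country), 1]

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.countries):
            a, b = self.ab[:, i, 0], self.ab[:, i, 1]
            rows.append((c, a.mean(), a.std(), b.mean(), b.std()))
        out = pd.DataFrame(
            rows,
            columns=["country", "intercept", "intercept_sd", "slope", "slope_sd"],
        )
        out.attrs["rho_mean"] = float(self.rho.mean())
        out.attrs["rho_ui"] = tuple(np.quantile(self.rho, [0.025, 0.975]))
        return out

    def level_draws(self, country: str, year: int) -> np.ndarray:
        """Smoothed national log-mean level per posterior draw."""
        i = self.countries.index(country)
        t = year - self.model.year_center
        return self.ab[:, i, 0] + self.ab[:, i, 1] * t

    def adjust(self, intakes: DrawFrame, factor: str) -> DrawFrame:
        """Replace first-stage country-year levels with smoothed ones.

        Draw d of the adjusted stratum intake is the first-stage draw
        shifted (on the log scale) by the difference between the time
        model's level draw d and the first-stage posterior-mean level.
        Countries absent from the time-model fit keep their first-stage
        draws (logged).
        """
        series = national_log_series(intakes, factor).set_index(["country", "year"])
        sub = intakes.select(factor=factor)
        out = np.log(sub.draws.copy())
        skipped = set()
        for (country, year), rows in sub.index.groupby(["country", "year"]).groups.items():
            if country not in self.countries or (country, year) not in series.index:
                skipped.add(country)
                continue
            mhat = series.loc[(country, year), "value"]
            shift = self.level_draws(country, int(year)) - mhat
            out[list(rows)] += shift
        if skipped:
            logger.warning(
                "time adjustment skipped for countries %s (kept first-stage draws)",
                sorted(skipped),
            )
        return DrawFrame(sub.index, np.exp(out), dict(sub.meta))


def fit_time_model(
    intakes: DrawFrame,
    factor: str,
    covariates: pd.DataFrame | None = None,
    spec: TimeTrendSpec | None = None,
    seed: int = 0,
) -> TimeTrendResults:
    """Fit the varying-slopes model to first-stage intake draws.

    If a covariate table (factor, country, year, value) is supplied, only
    country-years with covariate coverage are modelled; countries losing
    coverage fall back to first-stage draws at adjustment time.
    """
    table = national_log_series(intakes, factor)
    if covariates is not None:
        cov = covariates[covariates["factor"] == factor][["country", "year", "value"]]
        cov = cov.rename(columns={"value": "covariate"})
        merged = table.merge(cov, on=["country", "year"], how="left")
        dropped = merged[merged["covariate"].isna()]["country"].unique()
        if len(dropped):
            logger.warning(
                "countries %s missing covariate coverage; excluded from the "
                "time model", sorted(dropped),
            )
        table = merged.dropna(subset=["covariate"]).reset_index(drop=True)
    return TimeTrendModel(table, spec).fit(seed=seed)
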