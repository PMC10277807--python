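"""Cross-validation of the intake model: predicted versus observed.

Protocol: randomly partition the survey records into 5 folds (20%
holdout), fit the model on the remaining 80% and predict the held-out
records, repeating the whole procedure 5 times with fresh partitions.
Predicted values include the held-out record's method effect and its
(possibly collapsed) stratum design, so prediction and observation are
on the same footing.  Correlation and the calibration slope (observed
regressed on predicted) are computed on the log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import IntakeModel, ModelSpec

logger = logging.getLogger(__name__)


@dataclass
class CrossValResult:
    """Record-level predicted-vs-observed table plus per-fold summaries."""

    table: pd.DataFrame  # repeat, fold, factor, observed, predicted (log scale)
    folds: int
    repeats: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for (rep, fold), grp in self.table.groupby(["repeat", "fold"]):
            rows.append((rep, fold, *_corr_slope(grp)))
        rows.append((-1, -1, *_corr_slope(self.table)))  # pooled, flagged -1
        return pd.DataFrame(
            rows, columns=["repeat", "fold", "correlation", "calibration_slope"]
        )

    @property
    def pooled_correlation(self) -> float:
        return _corr_slope(self.table)[0]

    @property
    def pooled_calibration_slope(self) -> float:
        return _corr_slope(self.table)[1]


def _corr_slope(df: pd.DataFrame) -> tuple[float, float]:
    p, o = df["predicted"].to_numpy(), df["observed"].to_numpy()
    if len(p) < 3 or p.std() == 0:
        return np.nan, np.nan
    corr = float(np.corrcoef(p, o)[0, 1])
    slope = float(np.cov(p, o)[0, 1] / np.var(p, ddof=1))
    return corr, slope


def cross_validate(
    records: pd.DataFrame,
    region_of: dict[str, str],
    covariates: pd.DataFrame | None = None,
    weights: pd.DataFrame | None = None,
    spec: ModelSpec | None = None,
    folds: int = 5,
    holdout: float = 0.20,
    repeats: int = 5,
    seed: int = 0,
) -> CrossValResult:
    """Repeated k-fold cross-validation of the intake model."""
    if abs(folds * holdout - 1.0) > 1e-9:
        raise ValueError("holdout fraction must equal 1/folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    n = len(records)
    all_countries = set(records["country"])
    all_factors = set(records["factor"])
    rows = []
    for rep in range(repeats):
        assignment = _make_folds(records, folds, rng, all_countries, all_factors)
        for fold in range(folds):
            test = records[assignment == fold].reset_index(drop=True)
            train = records[assignment != fold].reset_index(drop=True)
            model = IntakeModel(train, region_of, covariates, weights, spec)
            results = model.fit(seed=seed * 1000 + rep * folds + fold)
            pred = _predict_for(model, results, test)
            block = pd.DataFrame(
                {
                    "repeat": rep,
                    "fold": fold,
                    "factor": test["factor"],
                    "observed": np.log(test["observed_mean"].to_numpy(float)),
                    "predicted": pred,
                }
            )
            rows.append(block.dropna(subset=["predicted"]))
        logger.info("cross-validation repeat %d/%d done", rep + 1, repeats)
    return CrossValResult(pd.concat(rows, ignore_index=True), folds, repeats)


def _make_folds(records, folds, rng, all_countries, all_factors) -> np.ndarray:
    """Random equal folds; reshuffled once if a fold empties a country or
    factor from the training data, then an error."""
    n = len(records)
    for attempt in range(2):
        perm = rng.permutation(n)
        assignment = np.empty(n, dtype=int)
        assignment[perm] = np.arange(n) % folds
        ok = True
        for fold in range(folds):
            train = records[assignment != fold]
            if set(train["country"]) != all_countries or set(train["factor"]) != all_factors:
                ok = False
                break
        if ok:
            return assignment
        logger.warning("fold emptied a country or factor; reshuffling once")
    raise ValueError("could not form folds retaining every country and factor")


def _predict_for(model: IntakeModel, results, test: pd.DataFrame) -> np.ndarray:
    """Posterior-mean log prediction for held-out records, including their
    method effect and collapsed-stratum design."""
    out = np.full(len(test), np.nan)
    for factor in test["factor"].unique():
        sub = test[test["factor"] == factor]
        tmp_model = IntakeModel(
            sub.reset_index(drop=True), model.region_of, model.covariates,
            model.weights, model.spec,
        )
        design = tmp_model._build_design(factor)
        # align held-out design columns with the fitted parameterization
        fit_cols = results.columns(factor)
        X = np.zeros((len(sub), len(fit_cols)))
        for j, name in enumerate(design.columns):
            if name in fit_cols:
                X[:, fit_cols.index(name)] = design.X[:, j]
            # a method or country present only in the holdout has no
            # fitted coefficient; its contribution is treated as zero
        loc_mean = results.loc_draws(factor).mean(axis=0)
        out[sub.index.to_numpy()] = X @ loc_mean
    return out
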