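"""Population-weighted aggregation of draw-level stratum scores.

Every estimate is formed draw-wise: for each of the 4,000 posterior
draws the included strata are averaged with normalized person weights,
and the median / 2.5th / 97.5th percentiles of the 4,000 aggregated
values give the estimate and its 95% uncertainty interval.  Differences
(between subgroups, or between 2018 and 1990) are likewise computed per
matched stratum per draw before aggregation, so the intervals reflect
the correlated uncertainty shared by both sides of the contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .draws import DrawFrame, summarize_draws
from .strata import ADULT_AGE_BANDS, CHILD_AGE_BANDS, STRATUM_COLUMNS

logger = logging.getLogger(__name__)

_KEY = ["country", "year"] + STRATUM_COLUMNS


@dataclass(frozen=True)
class AggregateEstimate:
    """A population-weighted estimate with its 95% UI."""

    scope: str  # 'global', a region name, or a country name
    pattern: str
    year: object  # a year or a (year_from, year_to) pair
    filter: str
    median: float
    ui_low: float
    ui_high: float
    draws: np.ndarray = None  # the 4,000 aggregated draws

    def __repr__(self) -> str:  # draws elided
        return (
            f"AggregateEstimate({self.scope!r}, {self.pattern!r}, {self.year!r}, "
            f"filter={self.filter!r}, median={self.median:.3f}, "
            f"ui=({self.ui_low:.3f}, {self.ui_high:.3f}))"
        )


def _resolve_filter(index: pd.DataFrame, flt: dict | None) -> np.ndarray:
    flt = dict(flt or {})
    keep = np.ones(len(index), dtype=bool)
    if "age_class" in flt:
        bands = CHILD_AGE_BANDS if flt.pop("age_class") == "children" else ADULT_AGE_BANDS
        keep &= index["age_group"].isin(bands).to_numpy()
    for col, val in flt.items():
        if isinstance(val, (list, tuple, set)):
            keep &= index[col].isin(list(val)).to_numpy()
        else:
            keep &= (index[col] == val).to_numpy()
    return keep


def _attach_weights(index: pd.DataFrame, weights: pd.DataFrame) -> np.ndarray:
    merged = index.merge(
        weights[_KEY + ["persons"]], on=_KEY, how="left", sort=False
    )
    w = merged["persons"].to_numpy(float)
    if np.isnan(w).any():
        raise ValueError("population weights missing for some included strata")
    return w


def _weighted_estimate(
    scores: DrawFrame, w: np.ndarray, scope: str, pattern: str, year, filt: str
) -> AggregateEstimate:
    if w.sum() <= 0:
        raise ValueError(f"filter selects zero population for scope {scope!r}")
    wn = w / w.sum()
    agg = wn @ scores.draws  # per-draw weighted mean
    med, lo, hi = summarize_draws(agg)
    return AggregateEstimate(scope, pattern, year, filt, float(med), float(lo), float(hi), agg)


def aggregate(
    scores: DrawFrame,
    weights: pd.DataFrame,
    scope: str = "global",
    filter: dict | None = None,
    region_of: dict[str, str] | None = None,
    year: int | None = None,
) -> list[AggregateEstimate]:
    """Population-weighted mean score per scope unit.

    ``scope`` is 'global', 'region' (requires ``region_of``) or
    'country'; ``filter`` restricts the aggregated population, e.g.
    ``{"sex": "female", "age_class": "adults"}``.
    """
    sub = scores if year is None else scores.select(year=year)
    keep = _resolve_filter(sub.index, filter)
    if not keep.any():
        raise ValueError("filter selects no strata")
    sub = DrawFrame(sub.index[keep], sub.draws[keep], dict(sub.meta))
    w = _attach_weights(sub.index, weights)
    filt = repr(filter or {})
    pattern = sub.index["pattern"].iloc[0] if "pattern" in sub.index else ""
    years = sorted(sub.index["year"].unique())
    ytag = years[0] if len(years) == 1 else tuple(years)

    if scope == "global":
        return [_weighted_estimate(sub, w, "global", pattern, ytag, filt)]
    if scope == "region":
        if region_of is None:
            raise ValueError("region scope requires region membership")
        groups = sub.index["country"].map(region_of)
    elif scope == "country":
        groups = sub.index["country"]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    out = []
    for name in sorted(groups.unique()):
        m = (groups == name).to_numpy()
        out.append(
            _weighted_estimate(
                DrawFrame(sub.index[m], sub.draws[m], dict(sub.meta)),
                w[m], name, pattern, ytag, filt,
            )
        )
    return out


#: contrast level pairs: (favoured, reference); the education contrast
#: drops the middle level entirely
CONTRAST_LEVELS = {
    "education": (">=12y", "<6y"),
    "urbanicity": ("urban", "rural"),
    "sex": ("female", "male"),
    "age_class": ("adults", "children"),
}


def contrast_groups(
    scores: DrawFrame,
    weights: pd.DataFrame,
    dimension: str,
    levels: tuple[str, str] | None = None,
    scope: str = "global",
    filter: dict | None = None,
    region_of: dict[str, str] | None = None,
    year: int | None = None,
) -> list[AggregateEstimate]:
    """Draw-wise subgroup difference (level_a minus level_b).

    The difference is formed per matched stratum pair (same country,
    year and all other demographic dimensions) per draw, then
    aggregated; a pair's weight is the summed person count of its two
    strata.  Unmatched strata are excluded with a logged count.
    """
    level_a, level_b = levels or CONTRAST_LEVELS[dimension]
    sub = scores if year is None else scores.select(year=year)
    keep = _resolve_filter(sub.index, filter)
    sub = DrawFrame(sub.index[keep], sub.draws[keep], dict(sub.meta))

    if dimension == "age_class":
        raise NotImplementedError(
            "age-class contrasts have no matched stratum pairs; aggregate "
            "each class separately instead"
        )
    match_cols = [c for c in _KEY if c != dimension]
    idx = sub.index
    w = _attach_weights(idx, weights)
    a_mask = (idx[dimension] == level_a).to_numpy()
    b_mask = (idx[dimension] == level_b).to_numpy()
    a = idx[a_mask].reset_index()
    b = idx[b_mask].reset_index()
    pairs = a.merge(b, on=match_cols, suffixes=("_a", "_b"))
    n_unmatched = (a_mask.sum() - len(pairs)) + (b_mask.sum() - len(pairs))
    if n_unmatched:
        logger.warning("%d strata had no contrast partner; excluded", n_unmatched)
    if len(pairs) == 0:
        raise ValueError("no matched stratum pairs for the contrast")
    ia = pairs["index_a"].to_numpy()
    ib = pairs["index_b"].to_numpy()
    diff = sub.draws[ia] - sub.draws[ib]
    pw = w[ia] + w[ib]
    pattern = idx["pattern"].iloc[0] if "pattern" in idx else ""
    pidx = pairs[match_cols].copy()
    pidx[dimension] = f"{level_a}-{level_b}"
    dframe = DrawFrame(pidx, diff, dict(sub.meta))
    filt = f"{dimension}: {level_a} - {level_b}"
    years = sorted(pidx["year"].unique())
    ytag = years[0] if len(years) == 1 else tuple(years)

    if scope == "global":
        return [_weighted_estimate(dframe, pw, "global", pattern, ytag, filt)]
    if scope == "region":
        groups = pidx["country"].map(region_of)
    elif scope == "country":
        groups = pidx["country"]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    out = []
    for name in sorted(groups.unique()):
        m = (groups == name).to_numpy()
        out.append(
            _weighted_estimate(
                DrawFrame(pidx[m], diff[m], dict(sub.meta)), pw[m], name,
                pattern, ytag, filt,
            )
        )
    return out


def change_over_time(
    scores_from: DrawFrame,
    scores_to: DrawFrame,
    weights_to: pd.DataFrame,
    scope: str = "global",
    filter: dict | None = None,
    region_of: dict[str, str] | None = None,
) -> list[AggregateEstimate]:
    """Draw-wise change between two years, standardized to the later
    year's population.

    The difference (to minus from) is taken per stratum per draw and
    aggregated with the later year's person weights only, so shifting
    demographics cannot masquerade as dietary change.
    """
    y_from = scores_from.index["year"].unique()
    y_to = scores_to.index["year"].unique()
    if len(y_from) != 1 or len(y_to) != 1:
        raise ValueError("each input must cover exactly one year")
    keep_f = _resolve_filter(scores_from.index, filter)
    keep_t = _resolve_filter(scores_to.index, filter)
    f = DrawFrame(scores_from.index[keep_f], scores_from.draws[keep_f])
    t = DrawFrame(scores_to.index[keep_t], scores_to.draws[keep_t])
    match = [c for c in _KEY if c != "year"]
    a = t.index.reset_index()
    b = f.index.reset_index()
    pairs = a.merge(b, on=match, suffixes=("_to", "_from"))
    if len(pairs) == 0:
        raise ValueError("no strata common to both years")
    diff = t.draws[pairs["index_to"].to_numpy()] - f.draws[pairs["index_from"].to_numpy()]
    pidx = pairs[match].copy()
    pidx["year"] = int(y_to[0])  # weights looked up at the target year
    w = _attach_weights(pidx[_KEY], weights_to)
    pattern = t.index["pattern"].iloc[0] if "pattern" in t.index else ""
    ytag = (int(y_from[0]), int(y_to[0]))
    filt = repr(filter or {})
    dframe = DrawFrame(pidx, diff)

    if scope == "global":
        return [_weighted_estimate(dframe, w, "global", pattern, ytag, filt)]
    if scope == "region":
        groups = pidx["country"].map(region_of)
    elif scope == "country":
        groups = pidx["country"]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    out = []
    for name in sorted(groups.unique()):
        m = (groups == name).to_numpy()
        out.append(
            _weighted_estimate(
                DrawFrame(pidx[m], diff[m]), w[m], name, pattern, ytag, filt
            )
        )
    return out


def estimates_frame(estimates: list[AggregateEstimate]) -> pd.DataFrame:
    """Tidy results table (scope, pattern, year, filter, median, UI)."""
    return pd.DataFrame(
        [
            (e.scope, e.pattern, str(e.year), e.filter, e.median, e.ui_low, e.ui_high)
            for e in estimates
        ],
        columns=["scope", "pattern", "year", "filter", "median", "ui_low", "ui_high"],
    )


def score_correlations(
    scores_by_pattern: dict[str, DrawFrame], year: int = 2018
) -> pd.DataFrame:
    """Spearman correlations between pattern scores across strata.

    Computed on stratum-level median scores of the given year; returns a
    symmetric matrix with unit diagonal.
    """
    meds = {}
    key_ref = None
    for pattern, frame in scores_by_pattern.items():
        sub = frame.select(year=year)
        sub_sorted = sub.index[_KEY].copy()
        order = sub_sorted.sort_values(_KEY).index.to_numpy()
        keys = sub.index[_KEY].iloc[order].reset_index(drop=True)
        if key_ref is None:
            key_ref = keys
        elif not key_ref.equals(keys):
            raise ValueError("patterns scored on different strata")
        meds[pattern] = sub.medians()[order]
    n = len(key_ref)
    if n < 3:
        raise ValueError("need at least 3 strata for a rank correlation")
    names = list(meds)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                rho = spearmanr(meds[a], meds[b]).statistic
                mat.loc[a, b] = mat.loc[b, a] = rho
    return mat
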