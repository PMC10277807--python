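"""Draw-level container and percentile conventions.

All uncertainty in the pipeline is carried as posterior draws: every
stratum-level quantity (an intake, a score) is a vector of N_DRAWS values,
and every summary is the 50th / 2.5th / 97.5th percentile of those draws.
Percentiles use linear interpolation between order statistics (numpy's
default), and the same convention is used everywhere, including the
independent sort-based oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: retained posterior draws; any other count downstream is a pipeline error
N_DRAWS = 4000

#: summary percentiles: median and the 95% uncertainty interval
SUMMARY_Q = (0.50, 0.025, 0.975)


def summarize_draws(draws: np.ndarray, axis: int = -1) -> tuple[np.ndarray, ...]:
    """Median, UI low, UI high of a draw vector (linear interpolation)."""
    med, lo, hi = np.quantile(draws, SUMMARY_Q, axis=axis)
    return med, lo, hi


def weighted_quantile(values, weights, q) -> np.ndarray:
    """Quantiles of a weighted empirical distribution.

    Uses the left-continuous inverse CDF: the quantile is the smallest
    value whose cumulative (normalized) weight reaches ``q``.  With equal
    weights this is the usual "type 1" sample quantile.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if values.shape != weights.shape:
        raise ValueError("values and weights must have the same shape")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order]) / total
    idx = np.searchsorted(cw, q, side="left")
    idx = np.clip(idx, 0, len(v) - 1)
    out = v[idx]
    return out if out.size > 1 else float(out[0])


@dataclass
class DrawFrame:
    """A table of draw vectors: an index DataFrame plus a draws matrix.

    ``index`` has one row per entity (e.g. a country-year-stratum-factor)
    and ``draws`` is the aligned ``(n_entities, n_draws)`` array.  Draw
    column ``d`` indexes the same joint posterior sample everywhere, which
    is what makes draw-wise differences meaningful.
    """

    index: pd.DataFrame
    draws: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or len(self.index) != self.draws.shape[0]:
            raise ValueError("index rows and draw rows must align")
        self.index = self.index.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.index)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def require_n_draws(self, n: int = N_DRAWS) -> "DrawFrame":
        if self.n_draws != n:
            raise ValueError(f"expected {n} draws per entity, found {self.n_draws}")
        return self

    def select(self, mask=None, **filters) -> "DrawFrame":
        """Subset rows by boolean mask and/or column == value filters."""
        keep = np.ones(len(self), dtype=bool) if mask is None else np.asarray(mask)
        for col, val in filters.items():
            if isinstance(val, (list, tuple, set, frozenset)):
                keep &= self.index[col].isin(list(val)).to_numpy()
            else:
                keep &= (self.index[col] == val).to_numpy()
        return DrawFrame(self.index[keep], self.draws[keep], dict(self.meta))

    def summary(self) -> pd.DataFrame:
        """Index columns plus median / ui_low / ui_high per row."""
        med, lo, hi = summarize_draws(self.draws, axis=1)
        out = self.index.copy()
        out["median"] = med
        out["ui_low"] = lo
        out["ui_high"] = hi
        return out

    def medians(self) -> np.ndarray:
        return np.quantile(self.draws, 0.5, axis=1)

    def to_long(self, value_name: str = "value") -> pd.DataFrame:
        """Long format: one row per (entity, draw_id)."""
        n, d = self.draws.shape
        rep = self.index.loc[self.index.index.repeat(d)].reset_index(drop=True)
        rep["draw_id"] = np.tile(np.arange(d), n)
        rep[value_name] = self.draws.reshape(-1)
        return rep

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        index_cols: list[str],
        value_name: str = "value",
        expected_draws: int | None = None,
    ) -> "DrawFrame":
        """Rebuild from long format.

        Entities keep their first-appearance order and draws are ordered
        by draw_id, so a write/read cycle is a faithful round trip.
        """
        if len(df) == 0:
            raise ValueError("empty draw table")
        keys = pd.MultiIndex.from_frame(df[index_cols])
        codes, _ = pd.factorize(keys)
        order = np.lexsort((df["draw_id"].to_numpy(), codes))
        df = df.iloc[order]
        counts = np.bincount(codes)
        if not np.all(counts == counts[0]):
            raise ValueError("unequal draw counts across entities")
        d = int(counts[0])
        if expected_draws is not None and d != expected_draws:
            raise ValueError(f"expected {expected_draws} draws, found {d}")
        index = df[index_cols].iloc[::d].reset_index(drop=True)
        draws = df[value_name].to_numpy(dtype=float).reshape(-1, d)
        return cls(index, draws)


def concat_drawframes(frames: list[DrawFrame]) -> DrawFrame:
    if not frames:
        raise ValueError("nothing to concatenate")
    d = frames[0].n_draws
    for f in frames:
        if f.n_draws != d:
            raise ValueError("draw counts differ across frames")
    return DrawFrame(
        pd.concat([f.index for f in frames], ignore_index=True),
        np.vstack([f.draws for f in frames]),
        dict(frames[0].meta),
    )
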