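"""Diet-quality scoring: AHEI, DASH and MED from declarative definitions.

Patterns are described by :class:`ScoreDefinition` objects loaded from
YAML: each component names a dietary factor, a direction (healthy or
unhealthy) and a scoring rule.  Three rules exist:

``cutpoint_linear``
    0 points at/beyond the worst cutpoint, 10 at/beyond the optimal one,
    linear in between (mirrored for unhealthy components).  Used by AHEI.
``quintile``
    1-5 points by sex-specific population quintile of the 2018
    standardized intake distribution, 5-1 for unhealthy components.
    Used by DASH.
``median_binary``
    1 point on the favourable side of the sex-specific 2018 population
    median, 0 otherwise.  Used by MED.

Empirical cutpoints (quintiles, medians) are computed once from the 2018
population-weighted distribution of stratum-level median intakes and
reused unchanged for every other year.  Ties at a quantile boundary take
the lower point value.  All scoring is applied per posterior draw, so
score uncertainty reflects intake uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .draws import DrawFrame, weighted_quantile
from .strata import SEXES, STRATUM_COLUMNS

logger = logging.getLogger(__name__)

RULES = ("cutpoint_linear", "quintile", "median_binary")
DIRECTIONS = ("healthy", "unhealthy")
QUINTILE_Q = (0.2, 0.4, 0.6, 0.8)

_KEY = ["country", "year"] + STRATUM_COLUMNS


@dataclass(frozen=True)
class Component:
    factor: str
    direction: str
    rule: str
    worst: float | None = None
    optimal: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}")
        if self.rule == "cutpoint_linear":
            if self.worst is None or self.optimal is None:
                raise ValueError("cutpoint_linear needs worst and optimal cutpoints")
            if self.worst == self.optimal:
                raise ValueError("worst and optimal cutpoints must differ")


@dataclass(frozen=True)
class ScoreDefinition:
    """One diet pattern: components plus the affine rescaling of the sum."""

    pattern: str
    components: tuple[Component, ...]
    rescale: tuple[int, int] = (1, 1)  # multiply the component sum by num/den
    reference_year: int = 2018

    @property
    def factors(self) -> list[str]:
        return [c.factor for c in self.components]

    @property
    def score_range(self) -> tuple[float, float]:
        lo = hi = 0.0
        for c in self.components:
            if c.rule == "cutpoint_linear":
                hi += 10.0
            elif c.rule == "quintile":
                lo += 1.0
                hi += 5.0
            else:
                hi += 1.0
        num, den = self.rescale
        return lo * num / den, hi * num / den


def load_definition(source: str | Path) -> ScoreDefinition:
    """Load a pattern definition: a builtin name (ahei/dash/med) or a
    YAML file path."""
    name = str(source).lower()
    if name in ("ahei", "dash", "med"):
        text = (resources.files("dietscore") / "data" / f"{name}.yaml").read_text()
    else:
        text = Path(source).read_text()
    raw = yaml.safe_load(text)
    comps = tuple(Component(**c) for c in raw["components"])
    return ScoreDefinition(
        pattern=raw["pattern"],
        components=comps,
        rescale=tuple(raw.get("rescale", (1, 1))),
        reference_year=int(raw.get("reference_year", 2018)),
    )


def score_component_linear(
    intake: np.ndarray, worst: float, optimal: float, direction: str
) -> np.ndarray:
    """0-10 linear component score, clamped at the cutpoints."""
    x = np.asarray(intake, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative intake passed to scoring")
    if direction == "healthy":
        s = (x - worst) / (optimal - worst) * 10.0
    else:
        s = (worst - x) / (worst - optimal) * 10.0
    return np.clip(s, 0.0, 10.0)


def score_component_quintile(
    intake: np.ndarray, boundaries: np.ndarray, direction: str
) -> np.ndarray:
    """1-5 points by quintile, 5-1 for unhealthy components.

    A value tied with a boundary is assigned the lower quintile, so the
    quintile index is direction-independent (for healthy components this
    is also the lower point value).
    """
    x = np.asarray(intake, dtype=float)
    b = np.asarray(boundaries, dtype=float)
    idx = 1.0 + (x[..., None] > b).sum(axis=-1)
    return idx if direction == "healthy" else 6.0 - idx


def score_component_median(
    intake: np.ndarray, median: float, direction: str
) -> np.ndarray:
    """0/1 against the population median; ties score 0."""
    x = np.asarray(intake, dtype=float)
    return (x > median).astype(float) if direction == "healthy" else (x < median).astype(float)


@dataclass
class CutpointSet:
    """Frozen empirical cutpoints of one pattern, per component and sex."""

    pattern: str
    year: int
    quintiles: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    medians: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pattern": self.pattern,
            "year": self.year,
            "quintiles": {
                f"{f}|{s}": [float(v) for v in b] for (f, s), b in self.quintiles.items()
            },
            "medians": {f"{f}|{s}": float(m) for (f, s), m in self.medians.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutpointSet":
        qs = {
            tuple(k.split("|")): np.asarray(v, dtype=float)
            for k, v in d.get("quintiles", {}).items()
        }
        ms = {tuple(k.split("|")): float(v) for k, v in d.get("medians", {}).items()}
        return cls(d["pattern"], int(d["year"]), qs, ms)


def compute_cutpoints(
    standardized: DrawFrame,
    weights: pd.DataFrame,
    definition: ScoreDefinition,
) -> CutpointSet:
    """Sex-specific quantile cutpoints from the reference-year population.

    Quantiles are taken over the stratum-level posterior-median intakes
    of the reference year, pooled across countries within sex and
    weighted by stratum person counts.
    """
    year = definition.reference_year
    ref = standardized.select(year=year)
    if len(ref) == 0:
        raise ValueError(f"no standardized intakes for reference year {year}")
    med = ref.index.copy()
    med["median_intake"] = ref.medians()
    med = med.merge(weights, on=["country", "year"] + STRATUM_COLUMNS, how="left")
    if med["persons"].isna().any():
        raise ValueError("population weights missing for some reference-year strata")
    cuts = CutpointSet(definition.pattern, year)
    for comp in definition.components:
        if comp.rule == "cutpoint_linear":
            continue
        sub = med[med["factor"] == comp.factor]
        if len(sub) == 0:
            raise ValueError(f"no reference-year intakes for factor {comp.factor!r}")
        for sex in SEXES:
            ss = sub[sub["sex"] == sex]
            vals = ss["median_intake"].to_numpy()
            w = ss["persons"].to_numpy()
            if comp.rule == "quintile":
                b = np.asarray(weighted_quantile(vals, w, QUINTILE_Q))
                if not np.all(np.diff(b) > 0):
                    logger.warning(
                        "degenerate quintile boundaries for %s (%s): %s",
                        comp.factor, sex, b,
                    )
                cuts.quintiles[(comp.factor, sex)] = b
            else:
                cuts.medians[(comp.factor, sex)] = float(
                    weighted_quantile(vals, w, 0.5)
                )
    return cuts


def score_strata(
    standardized: DrawFrame,
    definition: ScoreDefinition,
    cutpoints: CutpointSet | None = None,
    keep_components: bool = False,
) -> DrawFrame | tuple[DrawFrame, DrawFrame]:
    """Score every stratum per posterior draw.

    Returns the pattern-total DrawFrame (index: country, year, stratum
    columns, pattern); with ``keep_components`` also the per-component
    score DrawFrame.  Strata missing any component factor are not scored
    (logged), never partially scored.
    """
    needs_cuts = any(c.rule != "cutpoint_linear" for c in definition.components)
    if needs_cuts and cutpoints is None:
        raise ValueError(f"{definition.pattern} requires empirical cutpoints")
    if cutpoints is not None and needs_cuts:
        have = {f for f, _ in cutpoints.quintiles} | {f for f, _ in cutpoints.medians}
        need = {c.factor for c in definition.components if c.rule != "cutpoint_linear"}
        if not need <= have:
            raise ValueError(f"cutpoints missing for factors {sorted(need - have)}")

    idx = standardized.index
    keys = idx[_KEY].drop_duplicates().reset_index(drop=True)
    key_ix = pd.MultiIndex.from_frame(keys)
    pos_by_factor: dict[str, np.ndarray] = {}
    for comp in definition.components:
        sub = idx[idx["factor"] == comp.factor]
        lookup = pd.Series(sub.index.to_numpy(), index=pd.MultiIndex.from_frame(sub[_KEY]))
        pos_by_factor[comp.factor] = lookup.reindex(key_ix).to_numpy()

    complete = np.ones(len(keys), dtype=bool)
    for factor, pos in pos_by_factor.items():
        complete &= ~pd.isna(pos)
    if not complete.all():
        logger.warning(
            "%d strata missing at least one %s component factor; not scored",
            int((~complete).sum()), definition.pattern,
        )
    keys = keys[complete].reset_index(drop=True)
    nd = standardized.n_draws
    total = np.zeros((len(keys), nd))
    comp_frames = []
    sexes = keys["sex"].to_numpy()
    for comp in definition.components:
        rows = pos_by_factor[comp.factor][complete].astype(int)
        x = standardized.draws[rows]
        if comp.rule == "cutpoint_linear":
            s = score_component_linear(x, comp.worst, comp.optimal, comp.direction)
        else:
            s = np.empty_like(x)
            for sex in SEXES:
                m = sexes == sex
                if not m.any():
                    continue
                if comp.rule == "quintile":
                    s[m] = score_component_quintile(
                        x[m], cutpoints.quintiles[(comp.factor, sex)], comp.direction
                    )
                else:
                    s[m] = score_component_median(
                        x[m], cutpoints.medians[(comp.factor, sex)], comp.direction
                    )
        total += s
        if keep_components:
            cidx = keys.copy()
            cidx["pattern"] = definition.pattern
            cidx["component"] = comp.factor
            comp_frames.append(DrawFrame(cidx, s))
    num, den = definition.rescale
    total = total * (num / den)
    tidx = keys.copy()
    tidx["pattern"] = definition.pattern
    totals = DrawFrame(tidx, total, dict(standardized.meta))
    if keep_components:
        from .draws import concat_drawframes

        return totals, concat_drawframes(comp_frames)
    return totals
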