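"""Demographic strata: the joint sex x age x education x urbanicity cells.

Every country-year is partitioned into 264 strata: 2 sexes x 22 age bands
x 3 education levels x 2 urbanicity levels.  Age bands are <1, 1-2, 3-4,
5-9, then 5-year bands up to 90-94, and 95+; they are disjoint and cover
[0, inf).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

SEXES: tuple[str, ...] = ("male", "female")

EDUCATION_LEVELS: tuple[str, ...] = ("<6y", "6-<12y", ">=12y")

URBANICITY_LEVELS: tuple[str, ...] = ("urban", "rural")

# label -> (lower bound, upper bound) in years; upper bound exclusive,
# inf for the open-ended top band
_BANDS: list[tuple[str, float, float]] = (
    [("<1", 0.0, 1.0), ("1-2", 1.0, 3.0), ("3-4", 3.0, 5.0), ("5-9", 5.0, 10.0)]
    + [(f"{lo}-{lo + 4}", float(lo), float(lo + 5)) for lo in range(10, 95, 5)]
    + [("95+", 95.0, np.inf)]
)

AGE_BANDS: tuple[str, ...] = tuple(b[0] for b in _BANDS)
AGE_BOUNDS: dict[str, tuple[float, float]] = {b[0]: (b[1], b[2]) for b in _BANDS}

#: representative age for each band, used for age-effect evaluation
AGE_MIDPOINTS: dict[str, float] = {
    label: (lo + hi) / 2.0 if np.isfinite(hi) else lo + 2.5
    for label, (lo, hi) in AGE_BOUNDS.items()
}

#: children are <=19 years of age, adults >=20
CHILD_AGE_BANDS: tuple[str, ...] = tuple(
    label for label, (lo, hi) in AGE_BOUNDS.items() if hi <= 20.0
)
ADULT_AGE_BANDS: tuple[str, ...] = tuple(
    label for label in AGE_BANDS if label not in CHILD_AGE_BANDS
)

N_STRATA = len(SEXES) * len(AGE_BANDS) * len(EDUCATION_LEVELS) * len(URBANICITY_LEVELS)

#: sentinel used in survey records whose stratification collapsed a dimension
COLLAPSED = "all"


@dataclass(frozen=True, order=True)
class StratumKey:
    """One demographic cell: sex, age band, education, urbanicity."""

    sex: str
    age_group: str
    education: str
    urbanicity: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_group not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_group!r}")
        if self.education not in EDUCATION_LEVELS:
            raise ValueError(f"unknown education level {self.education!r}")
        if self.urbanicity not in URBANICITY_LEVELS:
            raise ValueError(f"unknown urbanicity {self.urbanicity!r}")

    @property
    def age_midpoint(self) -> float:
        return AGE_MIDPOINTS[self.age_group]

    @property
    def age_class(self) -> str:
        """'children' (<=19 y) or 'adults' (>=20 y)."""
        return "children" if self.age_group in CHILD_AGE_BANDS else "adults"


def age_band_of(age: float) -> str:
    """Return the band label containing ``age`` (years, >= 0)."""
    if age < 0:
        raise ValueError("age must be non-negative")
    for label, (lo, hi) in AGE_BOUNDS.items():
        if lo <= age < hi:
            return label
    return "95+"


def all_strata() -> list[StratumKey]:
    """All 264 strata in canonical (sex, age, education, urbanicity) order."""
    return [
        StratumKey(s, a, e, u)
        for s, a, e, u in product(SEXES, AGE_BANDS, EDUCATION_LEVELS, URBANICITY_LEVELS)
    ]


STRATUM_COLUMNS = ["sex", "age_group", "education", "urbanicity"]


def strata_frame() -> pd.DataFrame:
    """The 264 strata as a DataFrame in canonical order."""
    return pd.DataFrame(
        [(k.sex, k.age_group, k.education, k.urbanicity) for k in all_strata()],
        columns=STRATUM_COLUMNS,
    )
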