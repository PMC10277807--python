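"""Energy standardization: rescale intakes to a 2,000 kcal/day basis.

Diet-quality scores should reflect dietary composition, not quantity, so
before scoring every absolute-unit factor is rescaled draw-wise by the
density method: draw d of a factor in a stratum is multiplied by
2000 / (energy draw d of that stratum).  Energy itself maps to exactly
2,000 kcal; energy-relative units (% energy, ratios) are unchanged.
Applying the ratio per draw (rather than to summaries) keeps the joint
posterior structure intact, so ratios between two mass-unit factors are
preserved within each draw.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .draws import DrawFrame
from .strata import STRATUM_COLUMNS
from .world import RELATIVE_UNITS

logger = logging.getLogger(__name__)

TARGET_KCAL = 2000.0
ENERGY_FACTOR = "energy"

_KEY = ["country", "year"] + STRATUM_COLUMNS


def standardize_to_2000(
    intakes: DrawFrame,
    factor_units: dict[str, str],
    energy_factor: str = ENERGY_FACTOR,
    target: float = TARGET_KCAL,
) -> DrawFrame:
    """Rescale a stratum-level intake DrawFrame to ``target`` kcal/day.

    Strata without energy draws cannot be standardized and are excluded
    (with a logged reason) rather than scored on the wrong basis.
    """
    idx = intakes.index
    is_energy = (idx["factor"] == energy_factor).to_numpy()
    if not is_energy.any():
        raise ValueError(f"no {energy_factor!r} draws available for standardization")
    if np.any(intakes.draws[is_energy] <= 0):
        raise ValueError("energy draws must be strictly positive")

    energy_ix = (
        idx[is_energy].reset_index(drop=True).reset_index().set_index(_KEY)["index"]
    )
    stratum_keys = pd.MultiIndex.from_frame(idx[_KEY])
    pos = energy_ix.reindex(stratum_keys).to_numpy()
    missing = np.isnan(pos)
    if missing.any():
        dropped = idx[missing][_KEY].drop_duplicates()
        logger.warning(
            "excluding %d strata with no energy draws from standardization",
            len(dropped),
        )
    keep = ~missing
    energy_draws = intakes.draws[is_energy]

    units = idx["factor"].map(factor_units)
    if units.isna().any():
        raise ValueError(
            f"unknown units for factors {sorted(idx['factor'][units.isna()].unique())}"
        )
    relative = units.isin(RELATIVE_UNITS).to_numpy()

    out = intakes.draws[keep].copy()
    scale = target / energy_draws[pos[keep].astype(int)]
    mass = ~relative[keep] & ~is_energy[keep]
    out[mass] *= scale[mass]
    out[is_energy[keep]] = target  # exact by construction
    meta = dict(intakes.meta)
    meta["standardized"] = True
    meta["target_kcal"] = target
    return DrawFrame(idx[keep], out, meta)
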