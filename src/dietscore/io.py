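"""Readers, writers and run configuration.

Interchange dialect: plain UTF-8 CSV with '.' decimals, one JSON sidecar
(``<name>.meta.json``) per artifact carrying the schema version, draw
count, seed and generation parameters — enough to regenerate the file.
Draw-level tables are long format (one row per entity and draw), with
draw order preserved so that draw-wise differencing stays valid after a
round trip.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .draws import N_DRAWS, DrawFrame
from .strata import (
    COLLAPSED,
    EDUCATION_LEVELS,
    SEXES,
    STRATUM_COLUMNS,
    URBANICITY_LEVELS,
    AGE_BANDS,
)
from .surveys import METHODS, SURVEY_COLUMNS

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"


class SchemaError(ValueError):
    pass


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_sidecar(path: Path, **meta) -> None:
    meta = {"schema_version": SCHEMA_VERSION, **meta}
    _sidecar_path(Path(path)).write_text(json.dumps(meta, indent=2, default=str))


def read_sidecar(path: Path) -> dict:
    sp = _sidecar_path(Path(path))
    if not sp.exists():
        return {}
    meta = json.loads(sp.read_text())
    version = meta.get("schema_version")
    if version is not None and version != SCHEMA_VERSION:
        raise SchemaError(
            f"schema version mismatch: file is {version!r}, "
            f"this package reads {SCHEMA_VERSION!r}"
        )
    return meta


# -- surveys ------------------------------------------------------------
_VALID = {
    "sex": set(SEXES) | {COLLAPSED},
    "age_group": set(AGE_BANDS) | {COLLAPSED},
    "education": set(EDUCATION_LEVELS) | {COLLAPSED},
    "urbanicity": set(URBANICITY_LEVELS) | {COLLAPSED},
    "method": set(METHODS),
}


def write_surveys(records: pd.DataFrame, path: str | Path, **meta) -> None:
    path = Path(path)
    records[SURVEY_COLUMNS].to_csv(path, index=False)
    write_sidecar(path, kind="surveys", n_records=len(records), **meta)


def read_surveys(path: str | Path) -> pd.DataFrame:
    """Read and validate survey records; errors name offending rows."""
    path = Path(path)
    read_sidecar(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("survey file %s is empty", path)
        return pd.DataFrame(columns=SURVEY_COLUMNS)
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"survey file missing columns {sorted(missing)}")
    if len(df) == 0:
        logger.warning("survey file %s has no records", path)
        return df[SURVEY_COLUMNS]
    problems = []
    for col, valid in _VALID.items():
        bad = ~df[col].isin(valid)
        for row in df.index[bad]:
            problems.append(f"row {row}: invalid {col} {df.loc[row, col]!r}")
    for row in df.index[df["observed_mean"] <= 0]:
        problems.append(f"row {row}: observed_mean must be > 0")
    for row in df.index[df["observed_sd"] < 0]:
        problems.append(f"row {row}: observed_sd must be >= 0")
    for row in df.index[df["n"] < 1]:
        problems.append(f"row {row}: n must be >= 1")
    if problems:
        raise SchemaError(
            f"{len(problems)} invalid survey rows:\n" + "\n".join(problems[:20])
        )
    return df[SURVEY_COLUMNS]


# -- weights ------------------------------------------------------------
def write_weights(weights: pd.DataFrame, path: str | Path, **meta) -> None:
    path = Path(path)
    weights.to_csv(path, index=False)
    write_sidecar(path, kind="weights", **meta)


def read_weights(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    read_sidecar(path)
    df = pd.read_csv(path)
    need = {"country", "year", *STRATUM_COLUMNS, "persons"}
    missing = need - set(df.columns)
    if missing:
        raise SchemaError(f"weights file missing columns {sorted(missing)}")
    if (df["persons"] < 0).any():
        raise SchemaError("negative person counts in weights file")
    return df


# -- draw-level estimates (intakes and scores) --------------------------
def write_draws(frame: DrawFrame, path: str | Path, **meta) -> None:
    """Write a DrawFrame as long CSV plus sidecar (draw order preserved)."""
    path = Path(path)
    frame.to_long().to_csv(path, index=False)
    write_sidecar(
        path, kind="draws", n_draws=frame.n_draws, n_entities=len(frame),
        index_columns=list(frame.index.columns), **frame.meta, **meta,
    )


def read_draws(path: str | Path, expected_draws: int = N_DRAWS) -> DrawFrame:
    path = Path(path)
    meta = read_sidecar(path)
    df = pd.read_csv(path)
    index_cols = meta.get(
        "index_columns", [c for c in df.columns if c not in ("draw_id", "value")]
    )
    frame = DrawFrame.from_long(df, index_cols, expected_draws=expected_draws)
    frame.meta.update({k: v for k, v in meta.items() if k not in ("index_columns",)})
    return frame


# -- run configuration ---------------------------------------------------
@dataclass
class RunConfig:
    """Paths, stage toggles and seed for a pipeline run."""

    surveys: Path | None = None
    weights: Path | None = None
    covariates: Path | None = None
    definitions: dict[str, Path] = field(default_factory=dict)
    output_dir: Path = Path("output")
    seed: int = 0
    stages: tuple[str, ...] = ("fit", "standardize", "score", "aggregate")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            surveys=Path(raw["surveys"]) if "surveys" in raw else None,
            weights=Path(raw["weights"]) if "weights" in raw else None,
            covariates=Path(raw["covariates"]) if "covariates" in raw else None,
            definitions={k: Path(v) for k, v in raw.get("definitions", {}).items()},
            output_dir=Path(raw.get("output_dir", "output")),
            seed=int(raw.get("seed", 0)),
            stages=tuple(raw.get("stages", ("fit", "standardize", "score", "aggregate"))),
            log_level=raw.get("log_level", "INFO"),
        )
        for name, p in [("surveys", cfg.surveys), ("weights", cfg.weights),
                        ("covariates", cfg.covariates)]:
            if p is not None and not p.exists():
                raise FileNotFoundError(f"{name} file {p} does not exist")
        return cfg
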