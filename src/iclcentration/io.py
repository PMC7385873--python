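"""File formats and run configuration.

CSV is UTF-8, comma-separated, '.' decimal, mandatory header.  Every run
writes a manifest JSON carrying the seed and a hash of the full parameter
set, so downstream stages can detect mismatched inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .centration import RECORD_COLUMNS, CentrationRecord
from .errors import ConfigurationError, SchemaError
from .segmentation import SegmentationConfig
from .simulate import (
    CohortParams,
    EyeGeometry,
    RenderConfig,
    geometry_fields,
    geometry_from_row,
    geometry_to_row,
)

__all__ = [
    "RunConfig",
    "load_run_config",
    "config_hash",
    "write_geometries",
    "read_geometries",
    "write_records",
    "read_records",
    "write_manifest",
    "read_manifest",
]

METADATA_COLUMNS = ["eye_id", "laterality", "wtw_mm", "kappa_x_mm", "kappa_y_mm"]

MM_DECIMALS = 4


@dataclass(frozen=True)
class RunConfig:
    """Bundle of all stage parameters for one reproducible run."""

    cohort: CohortParams = field(default_factory=CohortParams)
    render: RenderConfig = field(default_factory=RenderConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    seed: int = 0
    log_level: str = "INFO"


def _replace_from_dict(obj, values: dict, section: str):
    valid = {f.name for f in dataclasses.fields(obj)}
    unknown = set(values) - valid
    if unknown:
        raise ConfigurationError(f"unknown {section} option(s): {sorted(unknown)}")
    return dataclasses.replace(obj, **values)


def load_run_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run config; missing sections fall back to defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("run config must be a YAML mapping")
    cfg = RunConfig(
        cohort=_replace_from_dict(CohortParams(), raw.get("cohort", {}), "cohort"),
        render=_replace_from_dict(RenderConfig(), raw.get("render", {}), "render"),
        segmentation=_replace_from_dict(
            SegmentationConfig(), raw.get("segmentation", {}), "segmentation"
        ),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
    cfg.cohort.validate()
    cfg.render.validate()
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of every parameter that affects outputs."""
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def write_geometries(path: str | Path, eyes: list[EyeGeometry]) -> None:
    df = pd.DataFrame([geometry_to_row(g) for g in eyes], columns=geometry_fields())
    df.to_csv(path, index=False)


def read_geometries(path: str | Path) -> list[EyeGeometry]:
    df = pd.read_csv(path)
    missing = set(geometry_fields()) - set(df.columns)
    if missing:
        raise SchemaError(f"geometry CSV missing column(s): {sorted(missing)}")
    return [geometry_from_row(row) for row in df.to_dict("records")]


def write_records(path: str | Path, records: list[CentrationRecord]) -> None:
    df = pd.DataFrame([r.to_row() for r in records], columns=RECORD_COLUMNS)
    mm_cols = [c for c in df.columns if c.endswith("_mm")]
    df[mm_cols] = df[mm_cols].round(MM_DECIMALS)
    df.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"records CSV {path} is empty") from exc
    if df.empty:
        raise SchemaError(f"records CSV {path} has a header but no rows")
    required = [c for c in RECORD_COLUMNS if not c.startswith(("kappa", "boundary"))]
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"records CSV missing column(s): {sorted(missing)}")
    for col in df.columns:
        if col.endswith("_mm"):
            bad = df[col].apply(lambda v: not _is_number(v))
            if bad.any():
                row = int(df.index[bad][0])
                raise SchemaError(f"non-numeric value in column {col!r}, row {row}")
    return df


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
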