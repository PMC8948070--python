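"""Reading, validating and writing the study-level data tables.

The canonical input is a UTF-8, comma-separated CSV with one row per
treatment-vs-control comparison (a study can contribute several rows:
multiple timepoints and/or tree size classes). Empty cells are explicit
missing values; unknown extra columns are carried through untouched so
supplementary covariates (e.g. a publication year) survive the pipeline.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: Mandatory columns of ``studies.csv``, in canonical order.
STUDY_COLUMNS: tuple[str, ...] = (
    "study_id",
    "comparison_id",
    "response_metric",
    "growth_is_relative",
    "mean_t",
    "sd_t",
    "n_t",
    "mean_c",
    "sd_c",
    "n_c",
    "months_since_removal",
    "n_species",
    "quality",
    "size_class",
    "region",
    "latitude",
    "elevation_m",
    "precip_mm_yr",
    "temp_c",
    "dry_season_months",
    "disturbance",
    "months_since_disturbance",
    "removal_method",
    "repeated_removal",
    "n_repeats",
    "months_disturbance_to_removal",
)

_NUMERIC_COLUMNS = (
    "mean_t", "sd_t", "n_t", "mean_c", "sd_c", "n_c",
    "months_since_removal", "n_species", "latitude", "elevation_m",
    "precip_mm_yr", "temp_c", "dry_season_months",
    "months_since_disturbance", "n_repeats", "months_disturbance_to_removal",
)
_BOOL_COLUMNS = ("growth_is_relative", "repeated_removal")

QUALITY_LEVELS = ("high", "medium", "low")
RESPONSE_METRICS = ("growth", "agb")
REGIONS = ("neotropics", "africa", "asia")
DISTURBANCES = ("none", "logged", "secondary", "logged+secondary")
REMOVAL_METHODS = ("whole_plot", "focal_tree")


class SchemaError(ValueError):
    """A structural problem with an input table (missing column, bad enum...)."""


class ParseError(ValueError):
    """A cell that could not be parsed, reported with its row number."""


@dataclass
class AnalysisConfig:
    """Settings for one analysis arm (growth or biomass).

    Parameters mirror the published workflow: Hedges g effect sizes,
    m=10 stochastic imputations of missing variances, a weighted mixed
    model with study as random intercept, and simple cross-imputation
    averaging of coefficients/SEs/dfs.
    """

    response_metric: str = "growth"
    effect_measure: str = "smd"
    m_imputations: int = 10
    master_seed: int = 0
    fixed_effects: Sequence[str] = field(
        default_factory=lambda: ["months_since_removal", "n_species", "quality"]
    )
    pooling_rule: str = "average"
    exclude_imputed_rows: bool = False
    exclude_study_ids: Sequence[str] = field(default_factory=list)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.response_metric not in RESPONSE_METRICS:
            raise SchemaError(f"unknown response_metric {self.response_metric!r}")
        if self.effect_measure not in ("smd", "md"):
            raise SchemaError(f"unknown effect_measure {self.effect_measure!r}")
        if self.m_imputations < 1:
            raise SchemaError("m_imputations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise SchemaError("alpha must lie in (0, 1)")
        if self.pooling_rule not in ("average", "rubin"):
            raise SchemaError(f"unknown pooling_rule {self.pooling_rule!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fixed_effects"] = list(self.fixed_effects)
        d["exclude_study_ids"] = list(self.exclude_study_ids)
        return d


def _parse_numeric(df: pd.DataFrame, col: str) -> pd.Series:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    blank = raw.isna() | (raw.astype(str).str.strip() == "")
    bad = out.isna() & ~blank
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ParseError(
            f"non-numeric value {raw[bad].iloc[0]!r} in column {col!r} (file row {row})"
        )
    return out


def _parse_bool(df: pd.DataFrame, col: str) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }
    raw = df[col].astype(str).str.strip().str.lower()
    out = raw.map(mapping)
    bad = out.isna() & (raw != "") & (raw != "nan")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ParseError(
            f"non-boolean value {df[col][bad].iloc[0]!r} in column {col!r} (file row {row})"
        )
    return out.astype(object)


def _check_enum(df: pd.DataFrame, col: str, levels: Sequence[str]) -> None:
    vals = df[col].dropna().astype(str)
    bad = ~vals.isin(levels)
    if bad.any():
        raise SchemaError(
            f"column {col!r} contains {vals[bad].iloc[0]!r}; allowed: {list(levels)}"
        )


def read_study_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a ``studies.csv``.

    Returns a DataFrame with one row per comparison, original row order,
    typed numeric/boolean columns, NaN for MISSING cells, and any extra
    columns preserved verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=True, skip_blank_lines=True)

    missing_cols = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {missing_cols}")

    for col in _NUMERIC_COLUMNS:
        df[col] = _parse_numeric(df, col)
    for col in _BOOL_COLUMNS:
        df[col] = _parse_bool(df, col)

    _check_enum(df, "response_metric", RESPONSE_METRICS)
    _check_enum(df, "quality", QUALITY_LEVELS)
    _check_enum(df, "region", REGIONS)
    _check_enum(df, "disturbance", DISTURBANCES)
    _check_enum(df, "removal_method", REMOVAL_METHODS)

    dup = df.duplicated(subset=["study_id", "comparison_id"])
    if dup.any():
        key = df.loc[dup, ["study_id", "comparison_id"]].iloc[0]
        raise SchemaError(
            "duplicate (study_id, comparison_id): "
            f"({key['study_id']!r}, {key['comparison_id']!r})"
        )

    for col, lo in (("n_t", 1), ("n_c", 1)):
        bad = df[col].dropna() < lo
        if bad.any():
            raise SchemaError(f"column {col!r} must be >= {lo}")
    for col in ("sd_t", "sd_c"):
        bad = df[col].dropna() < 0
        if bad.any():
            raise SchemaError(f"column {col!r} must be >= 0 when present")

    return df.reset_index(drop=True)


def validate_study_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory study table by round-tripping the same checks."""
    missing_cols = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {missing_cols}")
    dup = df.duplicated(subset=["study_id", "comparison_id"])
    if dup.any():
        raise SchemaError("duplicate (study_id, comparison_id) keys")
    return df


# CSVs are written with 12 significant digits so a write/read round trip
# reproduces every float to the precision the downstream contracts promise.
_FLOAT_FORMAT = "%.12g"


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  config: AnalysisConfig | dict | None = None,
                  extra_manifest: dict | None = None) -> dict:
    """Write named result tables plus a JSON run manifest.

    Returns the manifest dict. File contents are deterministic for a fixed
    input; the timestamp lives only in the manifest's ``timestamp`` field.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    written: list[str] = []
    counts: dict[str, int] = {}
    for name, table in tables.items():
        fname = f"{name}.csv"
        table.to_csv(out_dir / fname, index=False, float_format=_FLOAT_FORMAT)
        written.append(fname)
        counts[name] = int(len(table))

    if isinstance(config, AnalysisConfig):
        config = config.to_dict()
    manifest = {
        "config": config,
        "tables": written,
        "row_counts": counts,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(out_dir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
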