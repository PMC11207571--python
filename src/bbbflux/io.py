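"""Shared tabular schemas, validated CSV I/O and pipeline configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .errors import SchemaError


@dataclass(frozen=True)
class TableSchema:
    """Required (typed) columns of a delimited-text table.

    Unknown columns are preserved on read and write; missing required
    columns raise :class:`SchemaError` naming them.
    """

    name: str
    columns: dict  # column -> dtype ('str', 'float', 'int')

    def validate(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{self.name} table is missing required column(s): {', '.join(missing)}"
            )
        out = df.copy()
        for col, dtype in self.columns.items():
            try:
                if dtype == "float":
                    out[col] = pd.to_numeric(out[col], errors="raise").astype(float)
                elif dtype == "int":
                    out[col] = pd.to_numeric(out[col], errors="raise").astype(int)
                else:
                    out[col] = out[col].astype(str)
            except (ValueError, TypeError) as exc:
                bad = _first_bad_row(df[col], dtype)
                raise SchemaError(
                    f"{self.name} table column '{col}' has a malformed value"
                    + (f" at data row {bad}" if bad is not None else "")
                ) from exc
        return out


def _first_bad_row(series: pd.Series, dtype: str):
    if dtype not in ("float", "int"):
        return None
    coerced = pd.to_numeric(series, errors="coerce")
    bad = coerced.isna() & series.notna()
    idx = bad.idxmax() if bad.any() else None
    return None if idx is None else int(idx) + 1  # 1-based, excluding header


WELL_SCHEMA = TableSchema(
    "wells",
    {
        "compound_id": "str",
        "cell_line": "str",
        "direction": "str",
        "inhibitor_arm": "str",
        "c0_donor_uM": "float",
        "t_end_min": "float",
        "amount_receiver_pmol": "float",
        "amount_donor_pmol": "float",
        "receiver_volume_mL": "float",
        "donor_volume_mL": "float",
        "filter_area_cm2": "float",
        "replicate_id": "int",
    },
)

LY_SCHEMA = TableSchema(
    "lucifer_yellow",
    {"compound_id": "str", "cell_line": "str", "ly_papp_cm_per_s": "float"},
)

ABUNDANCE_SCHEMA = TableSchema(
    "abundance",
    {"transporter": "str", "cell_abundance": "float", "brain_abundance": "float"},
)

KPUU_OBS_SCHEMA = TableSchema(
    "kpuu_observations",
    {
        "compound_id": "str",
        "net_er_mdr1": "float",
        "net_er_bcrp": "float",
        "kpuu_invivo": "float",
    },
)

DOSE_RESPONSE_SCHEMA = TableSchema(
    "dose_response",
    {
        "inhibitor_id": "str",
        "substrate": "str",
        "cell_line": "str",
        "concentration_uM": "float",
        "er": "float",
        "vehicle_er": "float",
    },
)


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read and schema-validate a CSV; extra columns pass through."""
    df = pd.read_csv(path)
    return schema.validate(df)


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Thresholds and fit settings with the study's defaults."""

    ly_papp_limit: float = 2e-6
    recovery_limit_pct: float = 60.0
    er_cutoff_single: float = 2.0
    er_cutoff_total: float = 3.0
    kpuu_cutoff: float = 0.3
    kpuu_cap: float = 1.2
    fold_threshold: float = 3.0
    resid_z_threshold: float = 2.0
    n_starts: int = 250
    start_range: tuple = (0.0, 5.0)
    #: the pipeline fits the scaling factors on log10 K_p,uu by default:
    #: in vivo values span orders of magnitude with multiplicative error,
    #: under which the natural-scale fit is unstable (see methods note)
    fit_log_scale: bool = True
    comparison_scale: str = "log10"
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("fit_log_scale", "comparison_scale", "start_range", "seed"):
                continue
            if isinstance(v, (int, float)) and v <= 0:
                raise SchemaError(f"pipeline threshold {f.name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "start_range" in data:
            data["start_range"] = tuple(data["start_range"])
        return cls(**data)

    def to_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        out["start_range"] = list(out["start_range"])
        return out
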