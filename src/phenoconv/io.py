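"""Cohort-table I/O and run configuration.

Cohort tables are delimited text (CSV, or TSV for ``.tsv`` paths) with one
row per patient.  Mandatory columns: ``patient_id``, ``sex``, ``age``,
``main_drug``, ``cpz_equivalent_dose``, and at least one genotype source
(``diplotype`` or ``gPT``).  Empty strings and ``NA`` are missing values.
Unknown columns are preserved untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .alleles import gpt_from_diplotype
from .models import CONTINUOUS_OUTCOMES, ORDINAL_OUTCOMES

__all__ = [
    "SchemaError",
    "RunConfig",
    "MANDATORY_COLUMNS",
    "OUTCOME_COLUMNS",
    "read_cohort",
    "write_cohort",
    "ensure_gpt",
]

MANDATORY_COLUMNS = ["patient_id", "sex", "age", "main_drug", "cpz_equivalent_dose"]
OUTCOME_COLUMNS = [*CONTINUOUS_OUTCOMES, *ORDINAL_OUTCOMES]
_NA_TOKENS = ["", "NA", "NaN", "nan"]


class SchemaError(ValueError):
    """Raised when a cohort table violates the documented column dictionary."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), na_values=_NA_TOKENS, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table {path} is missing mandatory columns: {missing}")
    if "diplotype" not in df.columns and "gPT" not in df.columns:
        raise SchemaError(f"cohort table {path} needs a 'diplotype' or 'gPT' column")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].unique().tolist()
        raise SchemaError(f"duplicate patient_id values: {dupes}")
    df["patient_id"] = df["patient_id"].astype(str)
    for col in ("age", "cpz_equivalent_dose", "illness_duration"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False)


def ensure_gpt(df: pd.DataFrame, allele_table=None) -> pd.DataFrame:
    """Derive the gPT column from diplotypes where it is not supplied."""
    out = df.copy()
    if "gPT" not in out.columns:
        out["gPT"] = pd.NA
    needs = out["gPT"].isna()
    if needs.any():
        if "diplotype" not in out.columns:
            raise SchemaError("cannot derive gPT: no 'diplotype' column")
        out.loc[needs, "gPT"] = [
            gpt_from_diplotype(d, allele_table).value for d in out.loc[needs, "diplotype"]
        ]
    return out


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML-loadable, CLI-overridable)."""

    cohort_path: str | None = None  # None -> simulate
    inhibitor_table_path: str | None = None
    allele_table_path: str | None = None
    output_dir: str = "phenoconv_out"
    outcomes: list[str] = field(default_factory=lambda: list(OUTCOME_COLUMNS))
    drug_groups: list[str] | None = None  # None -> every main_drug level
    stratify_by_sex: bool = True
    bonferroni_family: int | None = None  # None -> per-family automatic
    seed: int = 0
    simulate_n: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
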