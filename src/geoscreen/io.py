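"""Plain-text I/O for cohort tables, dosage matrices and run configuration."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "write_dosage_tsv",
    "read_config",
    "write_json",
]

_REQUIRED_COHORT_COLUMNS = ("participant_id", "x_coord", "y_coord", "area_id")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV; validates the identifying/coordinate columns."""
    df = pd.read_csv(path, dtype={"participant_id": str, "area_id": str,
                                  "icd10_code": str})
    missing = [c for c in _REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks columns: {missing}")
    if "icd10_code" in df.columns:
        df["icd10_code"] = df["icd10_code"].fillna("")
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)


def write_dosage_tsv(dosages: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dosages.to_csv(path, sep="\t")


def read_config(path) -> dict:
    """Read a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=float)
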