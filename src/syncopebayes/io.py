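"""CSV / config readers and writers.

Conventions: UTF-8, comma-separated, header row required; a missing
categorical value is an empty field. Patient cohort tables have one row
per patient with columns ``patient_id``, ``population``, optionally
``true_class``, and one column per predictor.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .derivation import StudyCounts
from .datasets import study_counts_from_long
from .predictors import CANDIDATE_PREDICTORS, CLASSES, MISSING

_COUNT_COLUMNS = ["study_id", "predictor", "class", "level", "count"]


def read_study_counts(path) -> dict[str, list[StudyCounts]]:
    """Read a long-format count table into per-predictor study lists.

    Malformed rows raise ``ValueError`` with the offending row index so
    input problems are diagnosable from the command line.
    """
    df = pd.read_csv(path, keep_default_na=False)
    missing_cols = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    if df.empty:
        raise ValueError(f"{path}: no count rows")
    for idx, row in df.iterrows():
        if row["predictor"] not in CANDIDATE_PREDICTORS:
            raise ValueError(f"{path} row {idx}: unknown predictor {row['predictor']!r}")
        if row["class"] not in CLASSES:
            raise ValueError(f"{path} row {idx}: unknown class {row['class']!r}")
        try:
            count = int(row["count"])
        except (TypeError, ValueError):
            raise ValueError(f"{path} row {idx}: count {row['count']!r} is not an integer")
        if count < 0:
            raise ValueError(f"{path} row {idx}: negative count")
    df["count"] = df["count"].astype(int)
    return study_counts_from_long(df)


def read_cohort(path) -> pd.DataFrame:
    """Read a patient cohort CSV; empty fields become the MISSING sentinel."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "population" not in df.columns:
        raise ValueError(f"{path}: cohort needs a 'population' column")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_predictions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    df["posterior"] = df["posterior"].astype(float)
    return df


def read_config(path) -> dict:
    """Read a JSON or YAML mapping, by file extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def write_config(payload: dict, path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))
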