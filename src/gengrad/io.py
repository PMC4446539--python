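"""Dataset and config readers/writers plus run metadata.

The canonical on-disk dataset format is a comma-separated text file with
a header containing at least ``subject,d,u,y`` ('.' decimal, UTF-8);
extra columns are ignored.  Floats are written with 17 significant
digits so a write/read round trip is lossless.  Configs are plain
key-value documents (JSON or YAML by extension) whose keys are exactly
the ``SimulationConfig`` field names.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .simulate import DATASET_COLUMNS, SimulationConfig

__all__ = ["read_dataset", "write_dataset", "read_config", "write_config",
           "validate_dataset", "write_metadata"]


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Check types and the u-constant-within-subject invariant."""
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required column(s) {missing}")
    df = df[list(DATASET_COLUMNS)].copy()
    for col in ("d", "u", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(f"non-numeric value in column {col!r} at row {row}")
        df[col] = vals.astype(float)
    nun = df.groupby("subject")["u"].nunique()
    bad = nun.index[nun > 1].tolist()
    if bad:
        raise ValueError(f"covariate u varies within subject(s) {bad}; u must "
                         "be a subject-level variable")
    return df


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a long-format gradient dataset from CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    try:
        return validate_dataset(df)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


def write_dataset(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_config(path) -> SimulationConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return SimulationConfig.from_dict(d)


def write_config(config: SimulationConfig, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    else:
        path.write_text(json.dumps(config.to_dict(), indent=2) + "\n")


def write_metadata(path, **record) -> None:
    """Write a JSON sidecar with everything needed to re-run bit-identically."""
    from . import __version__
    record = {"gengrad_version": __version__, **record}
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
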