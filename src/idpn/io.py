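"""File-format contracts: CSV feature/edge tables, YAML configs, JSON metadata.

CSV with a header row is the interchange format throughout; readers match
columns by name and fail on unknown or missing names rather than guessing
positions.  Every run can write a metadata record of all effective
parameter values so a run is reproducible from its artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .features import FEATURE_NAMES, FLAG_COL, ID_COL, SEVERITY_COL, validate_feature_table
from .instruments import InstrumentSpec


def read_feature_table(path: str | Path, feature_names=FEATURE_NAMES) -> pd.DataFrame:
    table = pd.read_csv(path)
    known = {ID_COL, FLAG_COL, SEVERITY_COL, *feature_names}
    unknown = [c for c in table.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown columns in feature table: {unknown}")
    if FLAG_COL in table.columns:
        table[FLAG_COL] = table[FLAG_COL].astype(bool)
    return validate_feature_table(table, feature_names)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_feature_table(table).to_csv(path, index=False)


def read_instrument_spec(path: str | Path) -> InstrumentSpec:
    """Instrument configuration from YAML (keys: instrument_id, n_items,
    item_range, reverse_items, dimension_map, standardization)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return InstrumentSpec(
        instrument_id=raw["instrument_id"],
        n_items=int(raw["n_items"]),
        item_range=tuple(raw["item_range"]),
        reverse_items=frozenset(raw.get("reverse_items", [])),
        dimension_map={int(k): v for k, v in (raw.get("dimension_map") or {}).items()},
        standardization=raw.get("standardization", "none"),
    )


def write_run_metadata(path: str | Path, **params) -> None:
    record = {"package_version": __version__, **params}
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
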