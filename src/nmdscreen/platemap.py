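"""Plate map parsing: which compound or control sits in each well."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

ROLES = ("library", "positive_control", "negative_control", "empty")
REQUIRED_COLUMNS = ["plate_id", "well_id", "compound_id", "role"]


class PlateMapError(ValueError):
    pass


def load_plate_map(path: str | Path) -> pd.DataFrame:
    """Read and validate a plate map CSV (plate_id, well_id, compound_id, role)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PlateMapError(f"{path}: missing columns {missing}")
    bad_roles = sorted(set(df["role"]) - set(ROLES))
    if bad_roles:
        raise PlateMapError(f"{path}: unknown roles {bad_roles}; expected one of {ROLES}")
    dup = df.duplicated(subset=["plate_id", "well_id"])
    if dup.any():
        first = df.loc[dup, ["plate_id", "well_id"]].iloc[0]
        raise PlateMapError(
            f"{path}: duplicate well entry {first.plate_id}/{first.well_id}"
        )
    return df[REQUIRED_COLUMNS]
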