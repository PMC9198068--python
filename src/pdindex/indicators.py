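"""Derive the five deprivation indicators from raw household records.

All indicators are deprivation-oriented (higher = more deprived):

==================  =========================================================
share_toilet        number of *other* households sharing the toilet (0 = private)
public_water        1 if the only water access is a public/open source
persons_per_room    household members per sleeping room (rooms floored at 1)
no_ict              1 if no mobile phone in the household
no_vehicle          1 if no bicycle, motorbike or car
==================  =========================================================
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

#: Canonical indicator column order used by every downstream stage.
INDICATOR_COLUMNS = (
    "share_toilet", "public_water", "persons_per_room", "no_ict", "no_vehicle",
)

#: Raw household fields each indicator is derived from.
RAW_FIELDS = (
    "toilet_sharing_count", "water_public", "n_members",
    "n_sleeping_rooms", "has_mobile", "has_vehicle",
)


def derive_indicators(record: Mapping[str, float]) -> dict[str, float]:
    """Map one household record to its indicator vector.

    Sleeping rooms of zero are treated as one room, so persons-per-room is
    always defined and equals the member count for room-less households.
    """
    missing = [f for f in RAW_FIELDS if record.get(f) is None or
               (isinstance(record.get(f), float) and np.isnan(record[f]))]
    if missing:
        raise SchemaError(f"record missing required fields: {missing}")
    return {
        "share_toilet": float(record["toilet_sharing_count"]),
        "public_water": float(record["water_public"]),
        "persons_per_room": float(record["n_members"])
        / max(float(record["n_sleeping_rooms"]), 1.0),
        "no_ict": 1.0 - float(record["has_mobile"]),
        "no_vehicle": 1.0 - float(record["has_vehicle"]),
    }


def indicator_matrix(
    households: pd.DataFrame,
) -> tuple[np.ndarray, pd.Index, dict[str, int]]:
    """Vectorized indicator derivation with listwise deletion.

    Returns the n x 5 indicator matrix (columns in
    :data:`INDICATOR_COLUMNS` order), the household_id index of retained
    rows, and an exclusion report counting missing values per raw field.
    Incomplete records are dropped and logged, never imputed.
    """
    required = set(RAW_FIELDS) | {"household_id"}
    absent = sorted(required - set(households.columns))
    if absent:
        raise SchemaError(f"households table missing columns: {absent}")

    raw = households[list(RAW_FIELDS)].apply(pd.to_numeric, errors="coerce")
    report = {f: int(raw[f].isna().sum()) for f in RAW_FIELDS}
    complete = ~raw.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("excluded %d incomplete household records: %s",
                       n_dropped, {k: v for k, v in report.items() if v})
    kept = raw[complete]
    if len(kept) < 2:
        raise SchemaError(
            f"only {len(kept)} complete records; at least 2 are required to fit a PCA"
        )
    matrix = np.column_stack([
        kept["toilet_sharing_count"].to_numpy(float),
        kept["water_public"].to_numpy(float),
        kept["n_members"].to_numpy(float)
        / np.maximum(kept["n_sleeping_rooms"].to_numpy(float), 1.0),
        1.0 - kept["has_mobile"].to_numpy(float),
        1.0 - kept["has_vehicle"].to_numpy(float),
    ])
    ids = pd.Index(households.loc[complete[complete].index, "household_id"],
                   name="household_id")
    return matrix, ids, report
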