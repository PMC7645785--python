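"""CSV interfaces for trial tables and error maps.

All files are UTF-8, comma-separated, '.' decimal, header mandatory.
Coordinates round-trip losslessly to well below 1e-9 mm.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .error_maps import ErrorMap, frame_to_maps, maps_to_frame

__all__ = [
    "MATCHING_COLUMNS",
    "TRAJECTORY_COLUMNS",
    "SchemaError",
    "read_matching_trials",
    "write_matching_trials",
    "read_trajectory_trials",
    "write_trajectory_trials",
    "read_error_maps",
    "write_error_maps",
]

MATCHING_COLUMNS = [
    "subject_id",
    "experiment",
    "session",
    "trial_index",
    "target_row",
    "target_col",
    "target_x_mm",
    "target_y_mm",
    "hand_x_mm",
    "hand_y_mm",
]

TRAJECTORY_COLUMNS = [
    "subject_id",
    "session",
    "trial_index",
    "alpha",
    "beta",
    "sample_index",
    "t_s",
    "x_mm",
    "y_mm",
    "valid",
]

_MATCHING_NUMERIC = [
    "target_x_mm",
    "target_y_mm",
    "hand_x_mm",
    "hand_y_mm",
]
_TRAJECTORY_NUMERIC = ["alpha", "beta", "t_s", "x_mm", "y_mm"]


class SchemaError(ValueError):
    """A trial file violates the documented schema."""


def _check_schema(df: pd.DataFrame, required: list[str], numeric: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring extra columns {extra}", stacklevel=3)
    for col in numeric:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise SchemaError(f"{path}: non-numeric {col} at file row(s) {rows}")
        df[col] = pd.to_numeric(df[col])


def read_matching_trials(path: str | Path) -> pd.DataFrame:
    """Load a visual-matching trial table, validating its schema."""
    df = pd.read_csv(path)
    _check_schema(df, MATCHING_COLUMNS, _MATCHING_NUMERIC, path)
    dup = df.duplicated(["subject_id", "session", "target_row", "target_col"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:5]
        raise SchemaError(f"{path}: duplicate (subject, session, target) at row(s) {rows}")
    return df


def write_matching_trials(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_trajectory_trials(path: str | Path) -> pd.DataFrame:
    """Load a trajectory-trace table, validating its schema."""
    df = pd.read_csv(path)
    _check_schema(df, TRAJECTORY_COLUMNS, _TRAJECTORY_NUMERIC, path)
    return df


def write_trajectory_trials(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_error_maps(maps: dict[tuple, ErrorMap] | list[ErrorMap], path: str | Path) -> None:
    """Write maps as long CSV (subject_id, session, row, col, x_e_cm, y_e_cm)."""
    values = maps.values() if isinstance(maps, dict) else maps
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    maps_to_frame(values).to_csv(path, index=False)


def read_error_maps(path: str | Path) -> dict[tuple, ErrorMap]:
    frame = pd.read_csv(path)
    required = ["subject_id", "session", "row", "col", "x_e_cm", "y_e_cm"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return frame_to_maps(frame)
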